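"""Parameter identifiability via the Hessian of the negative log-likelihood.

At the ML estimate, the inverse Hessian approximates the parameter
covariance; normalising it gives inter-parameter correlations.  Strong
off-diagonal correlation between a model's rate and exponent means the two
trade off along a likelihood ridge and cannot be interpreted separately.

The Hessian is built by central finite differences with an absolute step
(default 1e-3) on natural-scale parameters.  Hessians can be non-invertible
when the estimate sits near a bound or on a likelihood plateau/ridge; such
subjects are counted and excluded from cohort averages.  For the CS model,
whose impatience parameter ``a`` is often close to zero relative to the
step, a refit with the optimiser variable rescaled to 100*a (the model
evaluates a'/100) typically restores invertibility without changing the
correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .likelihood import loglik_from_arrays, trials_to_arrays

__all__ = [
    "CorrelationResult",
    "HessianProbeError",
    "numerical_hessian",
    "correlation_from_hessian",
    "subject_correlation",
    "cohort_mean_correlations",
]

STEP_DEFAULT = 1e-3
CONDITION_LIMIT = 1e8


class HessianProbeError(RuntimeError):
    """The objective returned a non-finite value at a finite-difference probe."""


@dataclass
class CorrelationResult:
    subject_id: str
    model_id: str
    hessian: np.ndarray
    invertible: bool
    condition_number: float
    correlation: Optional[np.ndarray]  # None when non-invertible
    rescaled_fit: bool = False


def numerical_hessian(objective: Callable[[np.ndarray], float],
                      point: np.ndarray, step: float = STEP_DEFAULT,
                      relative: bool = False) -> np.ndarray:
    """Central-difference Hessian of a scalar objective, symmetrised.

    ``relative=True`` scales the step per coordinate by max(|x_i|, 1).
    """
    x = np.asarray(point, dtype=float)
    n = x.size
    h = np.full(n, float(step))
    if relative:
        h = step * np.maximum(np.abs(x), 1.0)

    def f(offset: np.ndarray) -> float:
        val = objective(x + offset)
        if not np.isfinite(val):
            raise HessianProbeError(
                f"objective non-finite at offset {offset.tolist()}")
        return float(val)

    f0 = f(np.zeros(n))
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(ei) - 2.0 * f0 + f(-ei)) / (h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return (H + H.T) / 2.0


def correlation_from_hessian(hessian: np.ndarray):
    """Invert a Hessian to covariance, then normalise to correlations.

    Returns (invertible, condition_number, correlation-or-None).  The
    inversion is rejected (non-invertible, no correlation) when the
    Cholesky factorisation fails, the condition number exceeds 1e8, or the
    implied variances are non-positive.
    """
    H = np.asarray(hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    cond = float(np.linalg.cond(H))
    try:
        np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        return False, cond, None
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        return False, cond, None
    cov = np.linalg.inv(H)
    var = np.diag(cov)
    if np.any(var <= 0):
        return False, cond, None
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return True, cond, corr


def _objective_for_fit(fit, rescale_cs: bool):
    """Negative log-likelihood over natural-scale (discount params, beta)."""
    a_ss, a_ll, d_ll, chose_ll = trials_to_arrays(fit.trials)
    model_id = fit.model_id
    scale = 100.0 if (rescale_cs and model_id == "CS") else 1.0

    def neg_loglik(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        disc = theta[:-1].copy()
        disc[0] = disc[0] / scale
        if np.any(disc <= 0) or theta[-1] <= 0:
            return np.inf
        return -loglik_from_arrays(a_ss, a_ll, d_ll, chose_ll, model_id,
                                   disc, theta[-1])

    point = np.array(list(fit.params.discount_params) + [fit.params.beta])
    point[0] *= scale
    return neg_loglik, point


def subject_correlation(fit, step: float = STEP_DEFAULT,
                        rescale_cs: bool = False) -> CorrelationResult:
    """Hessian-based correlation diagnostics for one fitted subject.

    Beta is included in the Hessian (full 2x2 or 3x3), so the correlation
    matrix covers all free parameters; cohort summaries slice out the
    discounting-parameter block.
    """
    if not fit.trials:
        raise ValueError("FitResult carries no trial data")
    neg_loglik, point = _objective_for_fit(fit, rescale_cs)
    try:
        H = numerical_hessian(neg_loglik, point, step)
    except HessianProbeError:
        n = point.size
        return CorrelationResult(fit.subject_id, fit.model_id,
                                 np.full((n, n), np.nan), False,
                                 np.inf, None, rescale_cs)
    invertible, cond, corr = correlation_from_hessian(H)
    return CorrelationResult(fit.subject_id, fit.model_id, H, invertible,
                             cond, corr, rescale_cs)


def cohort_mean_correlations(fits: Sequence, step: float = STEP_DEFAULT,
                             rescale_cs: bool = False):
    """Average rate-exponent correlation per dual-parameter model.

    Averages the (rate, exponent) off-diagonal correlation over subjects
    with invertible Hessians only, and reports per-model bookkeeping of
    non-invertible counts.  When ``rescale_cs`` is set, CS Hessians are
    evaluated under the 100*a reparameterisation.

    Returns a DataFrame indexed by model with columns
    ``mean_corr``, ``n_invertible``, ``n_non_invertible``, ``n_total``.
    """
    per_model: Dict[str, List[float]] = {}
    counts: Dict[str, List[int]] = {}
    for fit in fits:
        res = subject_correlation(fit, step=step, rescale_cs=rescale_cs)
        m = fit.model_id
        counts.setdefault(m, [0, 0])
        if res.invertible and res.correlation is not None:
            counts[m][0] += 1
            if res.correlation.shape[0] >= 3:  # rate-exponent pair exists
                per_model.setdefault(m, []).append(float(res.correlation[0, 1]))
        else:
            counts[m][1] += 1
    if sum(c[0] for c in counts.values()) == 0:
        raise ValueError("no subject yielded an invertible Hessian")
    rows = []
    for m, (n_ok, n_bad) in counts.items():
        vals = per_model.get(m, [])
        rows.append({
            "model_id": m,
            "mean_corr": float(np.mean(vals)) if vals else np.nan,
            "n_invertible": n_ok,
            "n_non_invertible": n_bad,
            "n_total": n_ok + n_bad,
        })
    return pd.DataFrame(rows).set_index("model_id")
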