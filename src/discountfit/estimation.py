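"""Multi-start maximum-likelihood fitting of discount models.

Each (subject, model) pair is fit by maximising the softmax choice
log-likelihood with a derivative-free Nelder-Mead simplex, restarted from
``n_starts`` random starting points (default 20) to escape local optima.
All parameters are strictly positive, so the search runs on log-scale
(an unconstrained reparameterisation); values are clipped to the model's
bounds inside the objective and reported on natural scale, with
``boundary_flags`` marking estimates capped at a bound.

Starting values are drawn log-uniformly for rates (k, a) on [1e-4, 1] and
for beta on [0.1, 10], and uniformly for exponents (s, b) on [0.25, 2.5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import TrialRecord, loglik_from_arrays, trials_to_arrays
from .models import BETA_BOUNDS, ParamVector, get_model
from .selection import aic, bic

__all__ = [
    "FitResult",
    "EstimationFailureError",
    "fit_subject",
    "fit_cohort",
    "fits_to_frame",
]

N_STARTS_DEFAULT = 20
SIMPLEX_TOL = 1e-6
MAX_ITER = 5000
MIN_TRIALS_RECOMMENDED = 10

_START_RANGES = {
    "rate": (1e-4, 1.0),      # log-uniform
    "exponent": (0.25, 2.5),  # uniform
    "beta": (0.1, 10.0),      # log-uniform
}


class EstimationFailureError(RuntimeError):
    """All optimisation starts failed to produce a finite optimum."""


@dataclass
class FitResult:
    """Per-subject, per-model maximum-likelihood estimate.

    ``aic``/``bic`` count beta as a free parameter, so the single-rate
    models H and E have 2 free parameters and GM/R/CS have 3.  ``trials``
    keeps a reference to the fitted data so downstream diagnostics (e.g.
    the Hessian of the likelihood) can rebuild the objective.
    """

    subject_id: str
    model_id: str
    params: ParamVector
    loglik: float
    aic: float
    bic: float
    n_trials: int
    n_starts: int
    best_start_index: int
    converged: bool
    boundary_flags: Tuple[bool, ...]
    warnings: Tuple[str, ...] = ()
    trials: Tuple[TrialRecord, ...] = field(default=(), repr=False)

    @property
    def n_free(self) -> int:
        return get_model(self.model_id).n_params + 1


def _param_kinds(spec) -> List[str]:
    kinds = ["rate"]
    if spec.n_params == 2:
        kinds.append("exponent")
    kinds.append("beta")
    return kinds


def _draw_starts(spec, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """Starting points in log-parameter space, one row per start.

    Drawn start-by-start so that the first n starts of a larger request
    are identical to a smaller one (makes best-of-n monotone in n).
    """
    kinds = _param_kinds(spec)
    rows = np.empty((n_starts, len(kinds)))
    for i in range(n_starts):
        for j, kind in enumerate(kinds):
            lo, hi = _START_RANGES[kind]
            if kind == "exponent":
                rows[i, j] = np.log(rng.uniform(lo, hi))
            else:
                rows[i, j] = rng.uniform(np.log(lo), np.log(hi))
    return rows


def _bounds_matrix(spec) -> np.ndarray:
    rows = list(spec.default_bounds) + [BETA_BOUNDS]
    return np.asarray(rows, dtype=float)


def fit_subject(trials: Sequence[TrialRecord], model_id: str,
                n_starts: int = N_STARTS_DEFAULT, seed: int = 0,
                beta_convention: str = "temperature") -> FitResult:
    """Fit one model to one subject's trials by multi-start ML.

    Deterministic given (trials, model_id, n_starts, seed).  Degenerate
    subjects (all choices identical) yield boundary-flagged fits plus a
    warning, not an exception.
    """
    if len(trials) == 0:
        raise ValueError("trial list is empty")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    spec = get_model(model_id)
    notes: List[str] = []
    if len(trials) < MIN_TRIALS_RECOMMENDED:
        msg = (f"subject {trials[0].subject_id!r}: only {len(trials)} trials "
               f"(< {MIN_TRIALS_RECOMMENDED} recommended)")
        warnings.warn(msg)
        notes.append("low_trials")

    a_ss, a_ll, d_ll, chose_ll = trials_to_arrays(trials)
    if chose_ll.all() or (~chose_ll).all():
        notes.append("degenerate_choices")

    bounds = _bounds_matrix(spec)
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    def neg_loglik(x: np.ndarray) -> float:
        theta = np.exp(np.clip(x, log_lo, log_hi))
        return -loglik_from_arrays(a_ss, a_ll, d_ll, chose_ll, model_id,
                                   theta[:-1], theta[-1], beta_convention)

    rng = np.random.default_rng(seed)
    starts = _draw_starts(spec, n_starts, rng)

    best = None
    best_idx = -1
    any_converged = False
    for i in range(n_starts):
        res = minimize(neg_loglik, starts[i], method="Nelder-Mead",
                       options={"xatol": SIMPLEX_TOL, "fatol": SIMPLEX_TOL,
                                "maxiter": MAX_ITER, "maxfev": MAX_ITER})
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    if best is None:
        raise EstimationFailureError(
            f"all {n_starts} starts failed for subject "
            f"{trials[0].subject_id!r}, model {model_id}")

    x = np.clip(best.x, log_lo, log_hi)
    theta = np.exp(x)
    flags = tuple(bool(f) for f in
                  (np.isclose(x, log_lo, atol=1e-9) |
                   np.isclose(x, log_hi, atol=1e-9)))
    params = ParamVector(model_id, tuple(theta[:-1]), float(theta[-1]),
                         boundary_flags=flags)
    ll = -float(best.fun)
    n_free = spec.n_params + 1
    return FitResult(
        subject_id=trials[0].subject_id,
        model_id=model_id,
        params=params,
        loglik=ll,
        aic=aic(ll, n_free),
        bic=bic(ll, n_free, len(trials)),
        n_trials=len(trials),
        n_starts=n_starts,
        best_start_index=best_idx,
        converged=any_converged,
        boundary_flags=flags,
        warnings=tuple(notes),
        trials=tuple(trials),
    )


def fit_cohort(dataset: Dict[str, Sequence[TrialRecord]],
               models: Sequence[str] = ("H", "E", "GM", "R", "CS"),
               n_starts: int = N_STARTS_DEFAULT, seed: int = 0,
               beta_convention: str = "temperature") -> List[FitResult]:
    """Fit every model to every subject; one FitResult per (subject, model).

    Per-subject seeds are spawned deterministically from the master seed in
    subject order, so an identical dataset + seed reproduces the table
    exactly.  Per-subject failures are carried as flagged rows (loglik NaN)
    rather than aborting the cohort.
    """
    results: List[FitResult] = []
    subject_ids = list(dataset.keys())
    child_seeds = np.random.SeedSequence(seed).spawn(len(subject_ids))
    for sid, ss in zip(subject_ids, child_seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        for m in models:
            try:
                results.append(fit_subject(dataset[sid], m, n_starts,
                                           seed=sub_seed,
                                           beta_convention=beta_convention))
            except EstimationFailureError as err:
                spec = get_model(m)
                mid = np.sqrt(np.prod(np.asarray(spec.default_bounds), axis=1))
                results.append(FitResult(
                    subject_id=sid, model_id=m,
                    params=ParamVector(m, tuple(mid), 1.0),
                    loglik=float("nan"), aic=float("nan"), bic=float("nan"),
                    n_trials=len(dataset[sid]), n_starts=n_starts,
                    best_start_index=-1, converged=False,
                    boundary_flags=(False,) * (spec.n_params + 1),
                    warnings=("estimation_failed", str(err)),
                    trials=tuple(dataset[sid])))
    return results


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy table of fit results (one row per subject x model)."""
    rows = []
    for f in fits:
        row = {
            "subject_id": f.subject_id,
            "model_id": f.model_id,
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "n_trials": f.n_trials,
            "converged": f.converged,
            "warnings": ";".join(f.warnings),
        }
        row.update(f.params.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
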