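"""Indifference-point extraction and discount-curve fitting.

An indifference point is the delayed amount judged equal in value to the
fixed immediate reward (20 EUR here) at a given delay; its normalisation,
the discount fraction amount_ss / indifference_amount, lies in (0, 1] and
is what the discount curves are fit to — with fractions, the amount drops
out of every model and the curve is SV(A=1, D).

Indifference amounts from the adaptive (adjusting-amount) task are defined
as the midpoint of the terminal staircase bracket: the lowest delayed
amount the subject accepted and the highest it rejected.  Curves are fit by
multi-start nonlinear least squares, and goodness-of-fit is reported as
R^2 = 1 - SS_res / SS_tot about the mean fraction (negative values are
reported as computed, never clipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .models import get_model, subjective_value

__all__ = [
    "IndifferencePoint",
    "CurveFit",
    "staircase_indifference",
    "fit_indifference_curve",
    "group_median_points",
]

AMOUNT_SS_DEFAULT = 20.0


@dataclass(frozen=True)
class IndifferencePoint:
    delay: float                  # days
    indifference_amount: float    # euros
    fraction: float               # amount_ss / indifference_amount

    @classmethod
    def from_amount(cls, delay: float, indifference_amount: float,
                    amount_ss: float = AMOUNT_SS_DEFAULT):
        if indifference_amount < amount_ss:
            raise ValueError("indifference amount below the immediate amount")
        return cls(delay, indifference_amount,
                   amount_ss / indifference_amount)


@dataclass
class CurveFit:
    model_id: str
    params: Tuple[float, ...]
    r_squared: float
    residuals: np.ndarray


def staircase_indifference(session, amount_ss: float = AMOUNT_SS_DEFAULT
                           ) -> List[Optional[IndifferencePoint]]:
    """Indifference points from a terminated adaptive session.

    ``session`` is an AdaptiveSession (see the cohort module) carrying the
    terminal (lowest accepted, highest rejected) bracket per delay.  Delays
    whose staircase did not terminate yield None (flagged missing).
    """
    points: List[Optional[IndifferencePoint]] = []
    for block in session.blocks:
        if not block.terminated or block.bracket is None:
            points.append(None)
            continue
        lo_accept, hi_reject = block.bracket
        midpoint = (lo_accept + hi_reject) / 2.0
        points.append(IndifferencePoint.from_amount(
            block.delay, max(midpoint, amount_ss), amount_ss))
    return points


def _fraction_curve(model_id: str, params: np.ndarray,
                    delays: np.ndarray) -> np.ndarray:
    return np.asarray(subjective_value(model_id, params, 1.0, delays))


def fit_indifference_curve(points: Sequence[IndifferencePoint],
                           model_id: str, n_starts: int = 20,
                           seed: int = 0) -> CurveFit:
    """Least-squares fit of a discount model to fraction-vs-delay points.

    Multi-start trust-region least squares on log-scale parameters (same
    start distribution as the ML fitter); returns the best fit's natural-
    scale parameters, residuals, and R^2.
    """
    spec = get_model(model_id)
    pts = [p for p in points if p is not None]
    if len(pts) < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} points to fit {model_id}")
    delays = np.array([p.delay for p in pts], dtype=float)
    fracs = np.array([p.fraction for p in pts], dtype=float)

    bounds = np.asarray(spec.default_bounds, dtype=float)
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    def resid(logp: np.ndarray) -> np.ndarray:
        return _fraction_curve(model_id, np.exp(logp), delays) - fracs

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        start = np.empty(spec.n_params)
        start[0] = rng.uniform(np.log(1e-4), np.log(1.0))
        if spec.n_params == 2:
            start[1] = np.log(rng.uniform(0.25, 2.5))
        try:
            res = least_squares(resid, start, bounds=(log_lo, log_hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all curve-fit starts failed for {model_id}")

    params = tuple(np.exp(best.x))
    residuals = resid(best.x)
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((fracs - fracs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0
                                                   else -np.inf)
    return CurveFit(model_id=model_id, params=params, r_squared=r2,
                    residuals=residuals)


def group_median_points(cohort_points: Dict[str, Sequence[IndifferencePoint]]
                        ) -> List[IndifferencePoint]:
    """Per-delay median discount fraction across subjects.

    All subjects must share one delay grid; cohorts mixing grid sizes
    (e.g. six- vs seven-point subsets) must be split by the caller and
    aggregated per subgroup.  Even subject counts use the mean of the two
    central fractions.
    """
    grids = {tuple(p.delay for p in pts if p is not None)
             for pts in cohort_points.values()}
    if len(grids) != 1:
        raise ValueError(
            f"subjects have mismatched delay grids ({len(grids)} distinct); "
            "split the cohort by grid before aggregating")
    (grid,) = grids
    out = []
    for i, d in enumerate(grid):
        fracs = [
            [p for p in pts if p is not None][i].fraction
            for pts in cohort_points.values()
        ]
        med = float(np.median(fracs))
        out.append(IndifferencePoint(delay=d,
                                     indifference_amount=AMOUNT_SS_DEFAULT / med,
                                     fraction=med))
    return out
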