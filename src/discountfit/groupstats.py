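"""Group- and condition-level tests on discounting parameters.

Discounting parameters are heavily right-skewed, so parametric tests are
run on square-root transformed values: unlike the log transform, the
square root keeps a lower bound of 0 and tolerates estimates approaching
zero.  Rank tests are transform-invariant and are run on raw values.
Every comparison reports both a two-tailed t test (pooled-variance
two-sample with df = n1 + n2 - 2, or paired) and the matching Wilcoxon
variant (rank-sum or signed-rank).  Scaling exponents are additionally
tested against 1 (linear subjective time) with one-sample signed-rank
tests on exponent - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "sqrt_transform",
    "compare_parameter",
    "exponent_vs_one",
]


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    test_kind: str  # two_sample_t | paired_t | wilcoxon_signed_rank | wilcoxon_rank_sum
    statistic: float
    df: Optional[float]
    p_value: float


def sqrt_transform(values) -> np.ndarray:
    """Elementwise square root; raises on negative input."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("square-root transform requires non-negative values")
    return np.sqrt(v)


def _signed_rank_p(d: np.ndarray):
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences zero; signed-rank p set to 1")
        return 0.0, 1.0
    res = stats.wilcoxon(d, alternative="two-sided", correction=True,
                         method="exact" if (d.size <= 25 and
                                            np.unique(np.abs(d)).size == d.size)
                         else "approx")
    return float(res.statistic), float(res.pvalue)


def compare_parameter(group_a, group_b, parameter: str = "param",
                      paired: bool = False, transform: str = "sqrt",
                      welch: bool = False):
    """Two-tailed t test plus matching Wilcoxon test on a parameter.

    ``transform`` ("sqrt" or "identity") applies to the parametric test
    only; ranks are unchanged by monotone transforms, so the Wilcoxon part
    always uses raw values.  Returns (t_result, wilcoxon_result).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(a.size, b.size) < 5:
        warnings.warn("fewer than 5 observations in a group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal lengths")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups; test degenerate")

    if transform == "sqrt":
        ta, tb = sqrt_transform(a), sqrt_transform(b)
    elif transform == "identity":
        ta, tb = a, b
    else:
        raise ValueError(f"unknown transform {transform!r}")

    if paired:
        t = stats.ttest_rel(ta, tb)
        t_res = ComparisonResult(parameter, "paired_t", float(t.statistic),
                                 float(a.size - 1), float(t.pvalue))
        w_stat, w_p = _signed_rank_p(a - b)
        w_res = ComparisonResult(parameter, "wilcoxon_signed_rank",
                                 w_stat, None, w_p)
    else:
        t = stats.ttest_ind(ta, tb, equal_var=not welch)
        df = float(a.size + b.size - 2) if not welch else float(t.df)
        t_res = ComparisonResult(parameter, "two_sample_t",
                                 float(t.statistic), df, float(t.pvalue))
        w = stats.mannwhitneyu(a, b, alternative="two-sided")
        w_res = ComparisonResult(parameter, "wilcoxon_rank_sum",
                                 float(w.statistic), None, float(w.pvalue))
    return t_res, w_res


def exponent_vs_one(exponents, parameter: str = "exponent") -> ComparisonResult:
    """One-sample Wilcoxon signed-rank test of scaling exponents against 1."""
    e = np.asarray(exponents, dtype=float)
    if e.size == 0:
        raise ValueError("no exponent values supplied")
    stat, p = _signed_rank_p(e - 1.0)
    return ComparisonResult(parameter, "wilcoxon_signed_rank", stat, None, p)
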