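"""Information-criterion scoring and model comparison.

AIC = -2*LL + 2*n_free and BIC = -2*LL + n_free*ln(n_trials), where n_free
counts the discounting parameters plus the softmax beta.  Because only
relative fit matters, scores are reported as deltas: each model's excess
over the best (lowest) score, per subject and for the group-summed scores,
so the best model sits at exactly 0.  Per-subject winners feed winner
frequencies, and pairwise differences in per-subject deltas are compared
with two-sided Wilcoxon signed-rank tests (the delta distributions are
heavily skewed, so a paired nonparametric test is appropriate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aic",
    "bic",
    "ScoreTable",
    "DeltaTable",
    "delta_scores",
    "winner_frequencies",
    "pairwise_wilcoxon",
    "scores_from_fits",
]

# Canonical model order; also the tie-break order after parameter count.
_MODEL_ORDER = ("H", "E", "GM", "R", "CS")
_N_FREE = {"H": 2, "E": 2, "GM": 3, "R": 3, "CS": 3}


def aic(loglik: float, n_free: int) -> float:
    """Akaike information criterion."""
    if n_free < 1:
        raise ValueError("n_free must be >= 1")
    return -2.0 * loglik + 2.0 * n_free


def bic(loglik: float, n_free: int, n_trials: int) -> float:
    """Bayesian information criterion (penalty n_free * ln n_trials)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return -2.0 * loglik + n_free * math.log(n_trials)


@dataclass
class ScoreTable:
    """(subject x model) matrix of AIC or BIC scores."""

    scores: pd.DataFrame  # index: subject_id, columns: model_id
    score_kind: str = "AIC"

    def __post_init__(self) -> None:
        if self.score_kind not in ("AIC", "BIC"):
            raise ValueError("score_kind must be 'AIC' or 'BIC'")


@dataclass
class DeltaTable:
    """Min-centred scores: per-subject delta matrix, group delta, winners."""

    per_subject: pd.DataFrame
    group: pd.Series
    winner: pd.Series
    score_kind: str = "AIC"


def scores_from_fits(fits, score_kind: str = "AIC") -> ScoreTable:
    """Pivot a list of FitResult into a ScoreTable."""
    col = score_kind.lower()
    rows = [(f.subject_id, f.model_id, getattr(f, col)) for f in fits]
    df = pd.DataFrame(rows, columns=["subject_id", "model_id", "score"])
    mat = df.pivot(index="subject_id", columns="model_id", values="score")
    order = [m for m in _MODEL_ORDER if m in mat.columns]
    return ScoreTable(mat[order], score_kind=score_kind)


def _tie_break_key(model_id: str) -> tuple:
    return (_N_FREE.get(model_id, 99), _MODEL_ORDER.index(model_id)
            if model_id in _MODEL_ORDER else 99)


def _argmin_with_ties(row: pd.Series) -> str:
    best = row.min()
    tied = [m for m in row.index if row[m] == best]
    return min(tied, key=_tie_break_key)


def delta_scores(scores: ScoreTable) -> DeltaTable:
    """Per-subject and group min-centred score differences.

    The group delta is computed on column sums (summed score per model
    across subjects), not by summing per-subject deltas.  Winners are the
    per-subject argmin; exact ties go to the model with fewer free
    parameters, then canonical order H < E < GM < R < CS.
    """
    mat = scores.scores
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete score table: missing cells for {bad}")
    per_subject = mat.sub(mat.min(axis=1), axis=0)
    col_sums = mat.sum(axis=0)
    group = col_sums - col_sums.min()
    winner = mat.apply(_argmin_with_ties, axis=1)
    return DeltaTable(per_subject=per_subject, group=group, winner=winner,
                      score_kind=scores.score_kind)


def winner_frequencies(delta: DeltaTable) -> pd.Series:
    """Proportion of subjects best fit by each model (sums to 1)."""
    counts = delta.winner.value_counts()
    freqs = counts.reindex(delta.per_subject.columns, fill_value=0)
    return freqs / freqs.sum()


def _signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p on paired samples.

    Zero differences are dropped (classical convention); exact null for
    n <= 25 without ties, continuity-corrected normal approximation above.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p set to 1")
        return 1.0
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) \
        else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", correction=True,
                         method=method)
    return float(res.pvalue)


def pairwise_wilcoxon(delta: DeltaTable, kind: str = "signed_rank",
                      holm: bool = False) -> pd.DataFrame:
    """Symmetric matrix of two-sided p-values on per-subject delta scores.

    ``kind`` is "signed_rank" (paired; the primary analysis — the same
    subjects are scored under every model) or "rank_sum" (independent
    Mann-Whitney, for comparison).  ``holm=True`` applies a Holm step-down
    correction across the upper triangle (off by default).
    """
    mat = delta.per_subject
    if len(mat) < 6:
        warnings.warn("fewer than 6 subjects: signed-rank p-values are coarse")
    models = list(mat.columns)
    p = pd.DataFrame(np.nan, index=models, columns=models)
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    raw = {}
    for a, b in pairs:
        if kind == "signed_rank":
            raw[(a, b)] = _signed_rank(mat[a].values, mat[b].values)
        elif kind == "rank_sum":
            raw[(a, b)] = float(stats.mannwhitneyu(
                mat[a].values, mat[b].values,
                alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test kind {kind!r}")
    if holm:
        keys = list(raw)
        pv = np.array([raw[k] for k in keys])
        order = np.argsort(pv)
        adj = np.empty_like(pv)
        running = 0.0
        m = len(pv)
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pv[idx])
            adj[idx] = min(1.0, running)
        raw = dict(zip(keys, adj))
    for (a, b), val in raw.items():
        p.loc[a, b] = val
        p.loc[b, a] = val
    return p
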