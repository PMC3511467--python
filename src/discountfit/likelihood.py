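"""Softmax choice rule and trial-wise log-likelihood.

Each trial is a binary choice between a smaller-sooner (SS) reward —
a fixed immediate amount — and a larger-later (LL) reward.  Under a given
discount model the probability of choosing LL follows a logistic (softmax)
function of the subjective-value difference,

    P(LL) = 1 / (1 + exp(-(SV_LL - SV_SS) / beta)),

where ``beta`` is a temperature: larger beta means a shallower sigmoid and
noisier (more stochastic) choices.  The alternative inverse-temperature
convention, P(LL) = logistic(beta * (SV_LL - SV_SS)), is available through
``beta_convention="multiplier"`` for sensitivity checks.

The dataset log-likelihood is the sum over trials of the log-probability of
the option actually chosen.  Probabilities are clipped to
[P_FLOOR, 1 - P_FLOOR] before logging so a near-deterministic subject cannot
produce -inf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .models import ParamVector, subjective_value

__all__ = [
    "TrialRecord",
    "LikelihoodValue",
    "P_FLOOR",
    "choice_probability",
    "dataset_log_likelihood",
    "trials_to_arrays",
]

P_FLOOR = 1e-12


@dataclass(frozen=True)
class TrialRecord:
    """One binary intertemporal choice."""

    subject_id: str
    amount_ss: float  # immediate reward, delay 0
    amount_ll: float  # delayed reward
    delay_ll: float   # days
    choice: str       # "SS" or "LL"

    def __post_init__(self) -> None:
        if not (self.amount_ll > self.amount_ss > 0):
            raise ValueError(
                f"require amount_ll > amount_ss > 0, got "
                f"SS={self.amount_ss}, LL={self.amount_ll}"
            )
        if self.delay_ll <= 0:
            raise ValueError("delay_ll must be > 0")
        if self.choice not in ("SS", "LL"):
            raise ValueError(f"choice must be 'SS' or 'LL', got {self.choice!r}")


@dataclass(frozen=True)
class LikelihoodValue:
    loglik: float
    n_trials: int


def _logistic(x):
    # log-sum-exp stable logistic: exp overflows are avoided by branching
    # on the sign of x.
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def choice_probability(sv_ss, sv_ll, beta, beta_convention="temperature"):
    """Probability of choosing the larger-later option.

    ``beta_convention`` selects whether beta divides ("temperature", the
    default: larger beta = noisier) or multiplies ("multiplier") the value
    difference.
    """
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be strictly positive")
    diff = np.asarray(sv_ll, dtype=float) - np.asarray(sv_ss, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("subjective values must be finite")
    if beta_convention == "temperature":
        z = diff / beta
    elif beta_convention == "multiplier":
        z = diff * beta
    else:
        raise ValueError(f"unknown beta_convention {beta_convention!r}")
    p = _logistic(np.atleast_1d(z))
    return float(p[0]) if np.ndim(z) == 0 else p


def trials_to_arrays(trials: Sequence[TrialRecord]):
    """Column arrays (amount_ss, amount_ll, delay_ll, chose_ll) for fast reuse."""
    a_ss = np.array([t.amount_ss for t in trials], dtype=float)
    a_ll = np.array([t.amount_ll for t in trials], dtype=float)
    d_ll = np.array([t.delay_ll for t in trials], dtype=float)
    chose_ll = np.array([t.choice == "LL" for t in trials], dtype=bool)
    return a_ss, a_ll, d_ll, chose_ll


def loglik_from_arrays(a_ss, a_ll, d_ll, chose_ll, model_id, discount_params,
                       beta, beta_convention="temperature") -> float:
    """Log-likelihood on pre-extracted arrays (hot path for fitting)."""
    sv_ll = subjective_value(model_id, discount_params, a_ll, d_ll)
    p_ll = choice_probability(a_ss, sv_ll, beta, beta_convention)
    p_ll = np.clip(p_ll, P_FLOOR, 1.0 - P_FLOOR)
    p_chosen = np.where(chose_ll, p_ll, 1.0 - p_ll)
    return float(np.sum(np.log(p_chosen)))


def dataset_log_likelihood(trials: Sequence[TrialRecord], model_id: str,
                           params: ParamVector,
                           beta_convention: str = "temperature") -> LikelihoodValue:
    """Sum of log choice probabilities over all trials of one subject.

    The immediate option is taken at face value (delay 0), the delayed
    option is discounted under ``model_id`` with ``params``.
    """
    if len(trials) == 0:
        raise ValueError("trial list is empty")
    if params.model_id != model_id:
        raise ValueError("params.model_id does not match model_id")
    a_ss, a_ll, d_ll, chose_ll = trials_to_arrays(trials)
    ll = loglik_from_arrays(a_ss, a_ll, d_ll, chose_ll, model_id,
                            params.discount_params, params.beta,
                            beta_convention)
    return LikelihoodValue(loglik=ll, n_trials=len(trials))
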