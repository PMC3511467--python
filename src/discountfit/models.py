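"""Discount functions for intertemporal choice.

Five subjective-value functions commonly fit to human delay-discounting
data.  Each maps a reward ``amount`` (euros) and a ``delay`` (days) to a
subjective (discounted) value:

=====  =========================  ==========================
id     name                       SV(A, D)
=====  =========================  ==========================
H      hyperbolic                 A / (1 + k*D)
E      exponential                A * exp(-k*D)
GM     generalized hyperbola      A / (1 + k*D)**s
R      power-time hyperbolic      A / (1 + k*D**s)
CS     constant sensitivity       A * exp(-((a*D)**b))
=====  =========================  ==========================

H and E carry a single discount-rate parameter ``k``.  GM raises the whole
hyperbolic denominator to a power ``s`` (equivalent to exponential
discounting on Weber-Fechner log-time); R raises only the delay to a power
``s`` (power-scaled subjective time); CS is an exponential-power form in
which ``a`` indexes impatience and ``b`` time sensitivity, with ``b = 1``
recovering exponential discounting.  Delays are real-valued days (sub-day
delays such as 0.25 are valid) and are never coerced to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "ParamVector",
    "InvalidModelError",
    "model_catalog",
    "get_model",
    "subjective_value",
]

MODEL_IDS = ("H", "E", "GM", "R", "CS")

# k and a share bounds, as do the exponents s and b; wide enough to cover
# empirical inter-quartile ranges with margin while keeping the likelihood
# finite.
RATE_BOUNDS = (1e-8, 10.0)
EXPONENT_BOUNDS = (0.01, 20.0)
BETA_BOUNDS = (1e-3, 100.0)


class InvalidModelError(ValueError):
    """Raised when a model id is not one of H, E, GM, R, CS."""


@dataclass(frozen=True)
class ModelSpec:
    """Metadata for one discount function.

    ``n_params`` counts discounting parameters only; the softmax
    stochasticity beta is always an additional free parameter at fit time.
    """

    model_id: str
    n_params: int
    param_names: Tuple[str, ...]
    default_bounds: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.n_params != len(self.param_names):
            raise ValueError("n_params must equal len(param_names)")
        for lo, hi in self.default_bounds:
            if not (0 < lo < hi):
                raise ValueError("bounds must be strictly positive intervals")


_CATALOG = (
    ModelSpec("H", 1, ("k",), (RATE_BOUNDS,)),
    ModelSpec("E", 1, ("k",), (RATE_BOUNDS,)),
    ModelSpec("GM", 2, ("k", "s"), (RATE_BOUNDS, EXPONENT_BOUNDS)),
    ModelSpec("R", 2, ("k", "s"), (RATE_BOUNDS, EXPONENT_BOUNDS)),
    ModelSpec("CS", 2, ("a", "b"), (RATE_BOUNDS, EXPONENT_BOUNDS)),
)
_BY_ID = {spec.model_id: spec for spec in _CATALOG}


def model_catalog() -> list[ModelSpec]:
    """Return the specs of the five models in canonical order H, E, GM, R, CS."""
    return list(_CATALOG)


def get_model(model_id: str) -> ModelSpec:
    try:
        return _BY_ID[model_id]
    except KeyError:
        raise InvalidModelError(
            f"unknown model id {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


@dataclass
class ParamVector:
    """A model's free parameters on natural scale.

    ``discount_params`` are ordered as in the model's ``param_names``
    (k, or a; then s or b where applicable); ``beta`` is the softmax
    stochasticity.  ``boundary_flags`` marks entries capped at a bound
    during fitting (discount params first, beta last).
    """

    model_id: str
    discount_params: Tuple[float, ...]
    beta: float
    boundary_flags: Tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        spec = get_model(self.model_id)
        self.discount_params = tuple(float(p) for p in self.discount_params)
        if len(self.discount_params) != spec.n_params:
            raise ValueError(
                f"model {self.model_id} takes {spec.n_params} discount "
                f"parameter(s), got {len(self.discount_params)}"
            )
        if any(p <= 0 for p in self.discount_params) or self.beta <= 0:
            raise ValueError("all parameters must be strictly positive")
        if not self.boundary_flags:
            self.boundary_flags = (False,) * (spec.n_params + 1)

    def as_dict(self) -> dict[str, float]:
        spec = get_model(self.model_id)
        out = dict(zip(spec.param_names, self.discount_params))
        out["beta"] = self.beta
        return out


def subjective_value(model_id, discount_params, amount, delay):
    """Subjective value of ``amount`` euros delivered after ``delay`` days.

    Vectorized over ``amount`` and ``delay``.  At ``delay == 0`` every model
    returns ``amount`` exactly (for CS with b < 1 the integrand (a*D)**b is
    taken at its limit 0).

    Raises
    ------
    InvalidModelError
        For an unknown model id.
    ValueError
        For non-positive amounts or negative delays.
    """
    spec = get_model(model_id)
    params = tuple(float(p) for p in np.atleast_1d(discount_params))
    if len(params) != spec.n_params:
        raise ValueError(
            f"model {model_id} takes {spec.n_params} discount parameter(s)"
        )
    A = np.asarray(amount, dtype=float)
    D = np.asarray(delay, dtype=float)
    if np.any(A <= 0):
        raise ValueError("amount must be strictly positive")
    if np.any(D < 0):
        raise ValueError("delay must be non-negative")

    if model_id == "H":
        k, = params
        sv = A / (1.0 + k * D)
    elif model_id == "E":
        k, = params
        sv = A * np.exp(-k * D)
    elif model_id == "GM":
        k, s = params
        sv = A / np.power(1.0 + k * D, s)
    elif model_id == "R":
        k, s = params
        sv = A / (1.0 + k * np.power(D, s))
    else:  # CS
        a, b = params
        # (a*D)**b -> 0 as D -> 0+ for any b > 0; np.power(0, b) honours
        # that limit for b > 0, so no special-casing beyond float conversion.
        sv = A * np.exp(-np.power(a * D, b))
    if np.ndim(amount) == 0 and np.ndim(delay) == 0:
        return float(sv)
    return sv
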