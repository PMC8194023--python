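"""Continuous-valued (nilpotent) logic primitives.

This module holds the mathematics underneath the logic layers of a LONN:

* the *squashing function* ``S_beta(x) = (1/beta) * ln((1 + e^{beta x}) /
  (1 + e^{beta (x-1)}))``, a differentiable, parametric approximation of the
  cutting function that tends to ``clamp(x, 0, 1)`` as ``|beta| -> inf``;
* its exact derivative ``S'_beta(x) = sigmoid(beta x) - sigmoid(beta (x-1))``;
* the cutting function itself; and
* the fixed weights/biases that realise Lukasiewicz-style (nilpotent) logical
  connectives as single perceptron units: conjunction ``max(0, sum(x) - (k-1))``,
  disjunction ``min(1, sum(x))``, negation ``1 - x``.

All functions accept scalars or numpy arrays and are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple, Union

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError, ShapeError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "GateKind",
    "GateSpec",
    "SquashingActivation",
    "cutting",
    "gate_apply",
    "gate_parameters",
    "squashing",
    "squashing_gradient",
]


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if beta == 0.0:
        raise InvalidParameterError("beta must be a nonzero real value")
    if not np.isfinite(beta):
        raise InvalidParameterError("beta must be finite")
    return beta


def _check_finite(x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("input must be finite")
    return arr


def _softplus(t: np.ndarray) -> np.ndarray:
    # log(1 + e^t) without overflow for large |t|
    return np.logaddexp(0.0, t)


def squashing(x: ArrayLike, beta: float) -> ArrayLike:
    """Evaluate the squashing function ``S_beta`` at ``x``.

    Computed as ``(softplus(beta*x) - softplus(beta*(x-1))) / beta``, which is
    identical to the logarithm-of-ratio form in exact arithmetic but does not
    overflow for large ``|beta * x|``.  Output lies strictly in ``(0, 1)`` for
    finite input; the function is increasing for ``beta > 0`` and decreasing
    for ``beta < 0``, and ``S_beta(0.5) = 0.5`` for every nonzero ``beta``.
    """
    beta = _check_beta(beta)
    arr = _check_finite(x)
    out = (_softplus(beta * arr) - _softplus(beta * (arr - 1.0))) / beta
    # the exact range is (0, 1); guard against one-ulp rounding excursions
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def squashing_gradient(x: ArrayLike, beta: float) -> ArrayLike:
    """Exact derivative ``dS_beta/dx = sigmoid(beta x) - sigmoid(beta (x-1))``.

    Strictly positive for ``beta > 0`` (negative for ``beta < 0``), with its
    extremum at ``x = 0.5``.
    """
    beta = _check_beta(beta)
    arr = _check_finite(x)
    from scipy.special import expit

    out = expit(beta * arr) - expit(beta * (arr - 1.0))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def cutting(x: ArrayLike) -> ArrayLike:
    """The cutting function ``clamp(x, 0, 1)`` — the sharp limit of ``S_beta``."""
    arr = _check_finite(x)
    out = np.clip(arr, 0.0, 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SquashingActivation:
    """The ``S_beta`` family with a fixed slope parameter.

    Parameters
    ----------
    beta : float
        Nonzero slope.  Large ``|beta|`` approaches the cutting function;
        negative ``beta`` mirrors the function about ``x = 0.5`` (a negation).
    """

    beta: float

    def __post_init__(self):
        object.__setattr__(self, "beta", _check_beta(self.beta))

    def __call__(self, x: ArrayLike) -> ArrayLike:
        return squashing(x, self.beta)

    def gradient(self, x: ArrayLike) -> ArrayLike:
        return squashing_gradient(x, self.beta)


class GateKind(str, Enum):
    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    NOR = "NOR"


def gate_parameters(kind: Union[GateKind, str], fan_in: int) -> Tuple[np.ndarray, float]:
    """Fixed perceptron weights and bias realising a nilpotent connective.

    ``AND`` -> weights all 1, bias ``-(fan_in - 1)`` (conjunction
    ``cut(sum x - (k-1))``); ``OR`` -> weights all 1, bias 0; ``NOT`` (unary
    only) -> weight -1, bias 1; ``NOR`` -> weights all -1, bias 1
    (``not(x) and not(y)``).  For two inputs these are exactly the published
    operator table rows.
    """
    if fan_in < 1:
        raise InvalidParameterError("fan_in must be a positive integer")
    try:
        kind = GateKind(kind.upper() if isinstance(kind, str) else kind)
    except ValueError:
        raise InvalidParameterError(f"unsupported gate kind: {kind!r}") from None
    if kind is GateKind.AND:
        return np.ones(fan_in), -(fan_in - 1.0)
    if kind is GateKind.OR:
        return np.ones(fan_in), 0.0
    if kind is GateKind.NOT:
        if fan_in != 1:
            raise InvalidParameterError("NOT is unary: fan_in must be 1")
        return -np.ones(1), 1.0
    # NOR = not(x1) and ... and not(xk) = cut(1 - sum x)
    return -np.ones(fan_in), 1.0


@dataclass(frozen=True)
class GateSpec:
    """An immutable logic gate: kind, fan-in, and the implied fixed parameters."""

    kind: GateKind
    fan_in: int
    weights: np.ndarray = field(init=False, repr=False)
    bias: float = field(init=False)

    def __post_init__(self):
        w, b = gate_parameters(self.kind, self.fan_in)
        w.setflags(write=False)
        object.__setattr__(self, "kind", GateKind(self.kind))
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)


def gate_apply(gate: GateSpec, inputs: ArrayLike, beta: float) -> float:
    """Evaluate a gate on fuzzy inputs: ``S_beta(w . x + b)``.

    For ``|beta| >= 50`` and crisp (0/1) inputs, rounding the result recovers
    the Boolean truth table.
    """
    arr = _check_finite(inputs).reshape(-1)
    if arr.shape[0] != gate.fan_in:
        raise ShapeError(
            f"gate expects {gate.fan_in} inputs, got {arr.shape[0]}"
        )
    return float(squashing(float(gate.weights @ arr) + gate.bias, beta))
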