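"""Neuronal activation (response) functions used as the CA update rule.

The rule maps the mean activity of a cell's neighborhood, ``a_in``, to the
cell's next state ``a_out``; it abstracts a neuron's firing-rate-vs-input
response curve.  Two approximations are provided:

* first-order (piecewise linear): zero outside the input window spanned by
  the thresholds ``a0`` and ``a1``, linear in between, saturating at ``a2``;
* second-order (saturating power law): zero below ``a0``, rising as
  ``a2 * (1 - (1 - u)**b)`` with ``u`` the rescaled input, with the upper
  input threshold fixed at 1.  ``b = 1`` recovers the linear rule.

All activities are dimensionless and live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LINEAR",
    "NONLINEAR",
    "ActivationParams",
    "InvalidParameterError",
    "linear_activation",
    "nonlinear_activation",
    "evaluate",
]

LINEAR = "linear"
NONLINEAR = "nonlinear"


class InvalidParameterError(ValueError):
    """Raised when activation parameters fall outside their valid ranges."""


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the CA activation rule.

    Attributes
    ----------
    a0 : float
        Lower input threshold, in [0, 1].
    a1 : float
        Upper input threshold, in [0, 1].  Fixed at 1 for the nonlinear rule.
    a2 : float
        Output saturation threshold, in [0, 1].
    b : float
        Nonlinearity exponent, >= 0.  Ignored by the linear rule; ``b = 1``
        makes the nonlinear rule coincide with the linear rule at ``a1 = 1``.
    order : str
        Rule selector, ``"linear"`` or ``"nonlinear"``.
    """

    a0: float
    a1: float = 1.0
    a2: float = 1.0
    b: float = 1.0
    order: str = LINEAR

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "a2"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise InvalidParameterError(
                    f"{name}={v!r} outside the valid range [0, 1]"
                )
        if not np.isfinite(self.b) or self.b < 0.0:
            raise InvalidParameterError(f"b={self.b!r} must be >= 0")
        if self.order not in (LINEAR, NONLINEAR):
            raise InvalidParameterError(f"unknown rule order {self.order!r}")
        if self.order == NONLINEAR and self.a1 != 1.0:
            raise InvalidParameterError(
                "the nonlinear rule fixes the upper input threshold a1 at 1"
            )

    @classmethod
    def linear(cls, a0: float, a1: float, a2: float) -> "ActivationParams":
        return cls(a0=a0, a1=a1, a2=a2, b=1.0, order=LINEAR)

    @classmethod
    def nonlinear(cls, a0: float, a2: float, b: float) -> "ActivationParams":
        return cls(a0=a0, a1=1.0, a2=a2, b=b, order=NONLINEAR)


def _as_array(a_in):
    x = np.asarray(a_in, dtype=float)
    return x, np.isscalar(a_in) or x.ndim == 0


def linear_activation(a_in, p: ActivationParams):
    """First-order activation rule.

    For ``a0 < a1`` (the generic response): zero outside the closed input
    window [a0, a1], linear interpolation ``a2 * (a_in - a0) / (a1 - a0)``
    inside it, saturating at ``a2``.  ``a0 = a1`` degenerates to the
    identically-zero map.

    Inverted threshold pairs: when ``0 < a1 < a0`` the rule's two zero
    branches (below the lower threshold, above the upper) cover every
    input, so the map is identically zero.  The boundary family ``a1 = 0``
    with ``a0 > 0`` is read as the negatively-sloped response
    ``a2 * (a0 - a_in) / a0`` on [0, a0] (zero above ``a0``) — the
    epileptic/oscillatory regime, where activity 0 maps to ``a2``.
    Output is clipped to [0, a2].
    """
    x, scalar = _as_array(a_in)
    if p.a0 == p.a1 or (p.a1 < p.a0 and p.a1 > 0.0):
        out = np.zeros_like(x)
        return float(out) if scalar else out
    lo, hi = min(p.a0, p.a1), max(p.a0, p.a1)
    out = p.a2 * (x - p.a0) / (p.a1 - p.a0)
    out = np.where((x >= lo) & (x <= hi), out, 0.0)
    out = np.clip(out, 0.0, p.a2)
    return float(out) if scalar else out


def nonlinear_activation(a_in, p: ActivationParams):
    """Second-order activation rule with upper input threshold fixed at 1.

    Zero below ``a0``; ``a2 * (1 - (1 - (a_in - a0)/(1 - a0))**b)`` for
    ``a_in >= a0``; saturates at ``a2`` at ``a_in = 1``.  At ``a0 = 1`` the
    rescaling is degenerate: the rule returns ``a2`` at ``a_in = 1`` and 0
    elsewhere.  Output is clipped to [0, a2].
    """
    x, scalar = _as_array(a_in)
    if p.a0 == 1.0:
        out = np.where(x >= 1.0, p.a2, 0.0)
        return float(out) if scalar else out
    u = (x - p.a0) / (1.0 - p.a0)
    # below-threshold inputs are masked out afterwards; clip keeps the power
    # well-defined there
    base = np.clip(1.0 - u, 0.0, 1.0)
    out = p.a2 * (1.0 - np.power(base, p.b))
    out = np.where(x >= p.a0, out, 0.0)
    out = np.clip(out, 0.0, p.a2)
    return float(out) if scalar else out


def evaluate(a_in, p: ActivationParams):
    """Evaluate the rule selected by ``p.order``."""
    if p.order == LINEAR:
        return linear_activation(a_in, p)
    return nonlinear_activation(a_in, p)
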