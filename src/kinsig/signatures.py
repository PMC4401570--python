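"""Parametric kinetic signature functions.

Five prototypical temporal response shapes are fitted to each expression
time course: an early peak, a late peak (same functional form, different
switch-time prior), a dip, an exponential decay and a linear trend.

Peak and dip are piecewise exponentials parameterised by the basal
expression ``p1`` (TPM), the maximal change in expression ``p2`` (TPM) and
the switch time ``t_s`` (minutes) at which 90% of the change is attained.
The rate constant ``delta`` is derived, never set directly:

* peak/dip: ``delta = ln(0.1) / t_s`` (negative), so the rising (peak) or
  falling (dip) phase covers 90% of ``p2`` by ``t = t_s``;
* decay: ``delta = ln(2) / t_h`` (positive), ``t_h`` the half-life of the
  excess expression ``p2`` above the basal level.

The linear model is parameterised by the expression at time 0 (``p1``) and
the total change over the observed window (``p2``); its value at time ``t``
is ``p1 + p2 * t / t_end``, so the slope is ``p2 / t_end``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignatureKind",
    "SignatureParams",
    "EXPONENTIAL_KINDS",
    "rate_from_switch_time",
    "rate_from_half_life",
    "evaluate",
]


class SignatureKind(str, enum.Enum):
    """The five kinetic signature categories."""

    EARLY_PEAK = "early_peak"
    LATE_PEAK = "late_peak"
    DIP = "dip"
    DECAY = "decay"
    LINEAR = "linear"

    @property
    def is_exponential(self) -> bool:
        return self is not SignatureKind.LINEAR

    @property
    def is_peak(self) -> bool:
        return self in (SignatureKind.EARLY_PEAK, SignatureKind.LATE_PEAK)

    @property
    def timing_parameter(self) -> str | None:
        """Name of the kind's timing parameter (``t_s``, ``t_h`` or None)."""
        if self.is_peak or self is SignatureKind.DIP:
            return "t_s"
        if self is SignatureKind.DECAY:
            return "t_h"
        return None


#: Exponential kinds, in canonical order.
EXPONENTIAL_KINDS = (
    SignatureKind.EARLY_PEAK,
    SignatureKind.LATE_PEAK,
    SignatureKind.DIP,
    SignatureKind.DECAY,
)


class InvalidParameterError(ValueError):
    """Raised for parameters outside a signature's domain."""


def rate_from_switch_time(t_s: float) -> float:
    """Rate constant ``delta = ln(0.1)/t_s`` for peak and dip signatures.

    Negative by construction: the exponential phase approaches its plateau
    and passes 90% of the way there exactly at ``t_s``.
    """
    if not t_s > 0:
        raise InvalidParameterError(f"switch time must be positive, got {t_s!r}")
    return math.log(0.1) / t_s


def rate_from_half_life(t_h: float) -> float:
    """Rate constant ``delta = ln(2)/t_h`` for the decay signature."""
    if not t_h > 0:
        raise InvalidParameterError(f"half-life must be positive, got {t_h!r}")
    return math.log(2.0) / t_h


@dataclass(frozen=True)
class SignatureParams:
    """Parameters of one kinetic signature.

    ``delta`` is computed from ``t_s`` or ``t_h``; the linear kind carries
    neither timing parameter nor rate. ``p2 >= 0`` for all exponential
    kinds (downregulation transients are modelled by dip/decay, not by
    inverted peaks); the linear kind allows signed ``p2``.
    """

    kind: SignatureKind
    p1: float
    p2: float
    t_s: float | None = None
    t_h: float | None = None

    def __post_init__(self) -> None:
        kind = SignatureKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not self.p1 >= 0:
            raise InvalidParameterError(f"basal expression p1 must be >= 0, got {self.p1!r}")
        if kind.is_exponential and not self.p2 >= 0:
            raise InvalidParameterError(
                f"p2 must be >= 0 for {kind.value} signatures, got {self.p2!r}"
            )
        if kind.is_peak or kind is SignatureKind.DIP:
            if self.t_s is None:
                raise InvalidParameterError(f"{kind.value} requires a switch time t_s")
            if self.t_h is not None:
                raise InvalidParameterError(f"{kind.value} does not take a half-life t_h")
            rate_from_switch_time(self.t_s)
        elif kind is SignatureKind.DECAY:
            if self.t_h is None:
                raise InvalidParameterError("decay requires a half-life t_h")
            if self.t_s is not None:
                raise InvalidParameterError("decay does not take a switch time t_s")
            rate_from_half_life(self.t_h)
        else:  # linear
            if self.t_s is not None or self.t_h is not None:
                raise InvalidParameterError("linear carries only p1 and p2")

    @property
    def delta(self) -> float | None:
        """Derived rate constant (1/min); ``None`` for the linear kind."""
        if self.kind.is_peak or self.kind is SignatureKind.DIP:
            return rate_from_switch_time(self.t_s)
        if self.kind is SignatureKind.DECAY:
            return rate_from_half_life(self.t_h)
        return None


def evaluate(params: SignatureParams, t, t_end: float | None = None):
    """Evaluate a signature at time(s) ``t`` (minutes since stimulation).

    Peak:  ``y = p1 + p2(1 - e^{dt})`` for ``t <= t_s``,
    ``y = p1 + 0.9 p2 - 0.9 p2 (1 - e^{d(t - t_s)})`` after, ``d = ln(0.1)/t_s``.
    Dip:   ``y = p1 + p2 e^{dt}`` for ``t <= t_s``,
    ``y = p1 + 0.1 p2 + 0.9 p2 (1 - e^{d(t - t_s)})`` after.
    Decay: ``y = p1 + p2 e^{-dt}``, ``d = ln(2)/t_h``.
    Linear: ``y = p1 + p2 t / t_end`` (``t_end`` required).

    Defined for continuous ``t >= 0``; accepts scalars or arrays and
    returns a matching float or ndarray.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    kind = params.kind
    if kind.is_peak or kind is SignatureKind.DIP:
        d = rate_from_switch_time(params.t_s)
        rising = t_arr <= params.t_s
        rel = t_arr - params.t_s
        if kind is SignatureKind.DIP:
            y = np.where(
                rising,
                params.p1 + params.p2 * np.exp(d * t_arr),
                params.p1 + 0.1 * params.p2 + 0.9 * params.p2 * (1.0 - np.exp(d * rel)),
            )
        else:
            y = np.where(
                rising,
                params.p1 + params.p2 * (1.0 - np.exp(d * t_arr)),
                params.p1 + 0.9 * params.p2 - 0.9 * params.p2 * (1.0 - np.exp(d * rel)),
            )
    elif kind is SignatureKind.DECAY:
        d = rate_from_half_life(params.t_h)
        y = params.p1 + params.p2 * np.exp(-d * t_arr)
    else:
        if t_end is None:
            raise InvalidParameterError("linear evaluation requires t_end (final observed time)")
        if not t_end > 0:
            raise InvalidParameterError(f"t_end must be positive, got {t_end!r}")
        y = params.p1 + params.p2 * t_arr / t_end
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(y)
    return y
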