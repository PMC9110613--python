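"""Tri-exponential time dose-rate curve (TDRC) model.

An organ's mean dose rate after a radiopharmaceutical injection is modelled
as the sum of three exponential phases — a fast uptake (negative amplitude),
a rapid washout and a long-term clearance — each decaying with the combined
physical + biological rate::

    TDRC(t) = -Omega1 * exp(-(lam + k1) t)
            +  Omega2 * exp(-(lam + k2) t)
            +  Omega3 * exp(-(lam + k3) t)

with ``lam`` the physical decay constant of the nuclide (177Lu here) and
``k1 > k2 > k3 >= 0`` the biological rate constants.  The time integral of
the curve over [0, inf) is the organ absorbed dose and has the closed form::

    D = -Omega1/(lam+k1) + Omega2/(lam+k2) + Omega3/(lam+k3)

Amplitudes are external dose rates in mGy/s, times in seconds internally
(hours at the I/O boundary), doses in Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LU177_HALF_LIFE_DAYS",
    "lu177_lambda",
    "TriExpParams",
    "MethodTag",
    "AbsorbedDose",
    "ParameterDomainError",
    "DivergentIntegralError",
    "evaluate_tdrc",
    "integrate_tdrc",
    "decay_correct",
    "decay_uncorrect",
    "HOURS_TO_SECONDS",
]

#: Physical half-life of 177Lu in days (evaluated nuclear-data value).
#: Overridable wherever a decay constant is accepted.
LU177_HALF_LIFE_DAYS = 6.6443

HOURS_TO_SECONDS = 3600.0
MGY_TO_GY = 1e-3


def lu177_lambda(half_life_days: float = LU177_HALF_LIFE_DAYS) -> float:
    """Physical decay constant (1/s) from a half-life in days."""
    if half_life_days <= 0:
        raise ParameterDomainError("half-life must be positive")
    return math.log(2.0) / (half_life_days * 86400.0)


class ParameterDomainError(ValueError):
    """Model parameters violate the tri-exponential invariants."""


class DivergentIntegralError(ParameterDomainError):
    """An effective rate lam + k_i is non-positive: the dose integral diverges."""


class MethodTag(str, Enum):
    """Provenance of a reported absorbed dose."""

    TRIEXP_REF = "TRIEXP_REF"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    MONOEXP = "MONOEXP"
    EXTRAPOLATED = "EXTRAPOLATED"


@dataclass(frozen=True)
class TriExpParams:
    """Six-parameter TDRC model plus the physical decay constant.

    Parameters
    ----------
    omega1, omega2, omega3:
        Phase amplitudes in mGy/s (all non-negative; the uptake term enters
        the curve with a minus sign).
    k1, k2, k3:
        Biological rate constants in 1/s with ``k1 > k2 > k3 >= 0``.
    lam:
        Physical decay constant in 1/s (> 0).
    """

    omega1: float
    omega2: float
    omega3: float
    k1: float
    k2: float
    k3: float
    lam: float = field(default_factory=lu177_lambda)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ParameterDomainError(f"lam must be > 0, got {self.lam}")
        for name, k in (("k1", self.k1), ("k2", self.k2), ("k3", self.k3)):
            if self.lam + k <= 0:
                raise DivergentIntegralError(
                    f"lam + {name} = {self.lam + k} <= 0: integral diverges"
                )
        if not (self.k1 > self.k2 > self.k3 >= 0):
            raise ParameterDomainError(
                f"rate ordering k1 > k2 > k3 >= 0 violated: "
                f"({self.k1}, {self.k2}, {self.k3})"
            )
        for name, w in (
            ("omega1", self.omega1),
            ("omega2", self.omega2),
            ("omega3", self.omega3),
        ):
            if w < 0:
                raise ParameterDomainError(f"{name} must be >= 0, got {w}")

    @property
    def rates(self) -> tuple[float, float, float]:
        """Effective decay rates lam + k_i (1/s)."""
        return (self.lam + self.k1, self.lam + self.k2, self.lam + self.k3)

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        """Signed amplitudes (-Omega1, Omega2, Omega3) in mGy/s."""
        return (-self.omega1, self.omega2, self.omega3)

    def is_zero_at_origin(self, rtol: float = 1e-12) -> bool:
        """True if Omega1 = Omega2 + Omega3, i.e. TDRC(0) = 0."""
        s = self.omega2 + self.omega3
        scale = max(abs(self.omega1), abs(s), 1e-300)
        return abs(self.omega1 - s) <= rtol * scale

    def to_record(self) -> dict:
        """Flat key-value record with unit-annotated field names (JSON-safe)."""
        return {
            "omega1_mGy_per_s": self.omega1,
            "omega2_mGy_per_s": self.omega2,
            "omega3_mGy_per_s": self.omega3,
            "k1_per_s": self.k1,
            "k2_per_s": self.k2,
            "k3_per_s": self.k3,
            "lambda_per_s": self.lam,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "TriExpParams":
        return cls(
            omega1=rec["omega1_mGy_per_s"],
            omega2=rec["omega2_mGy_per_s"],
            omega3=rec["omega3_mGy_per_s"],
            k1=rec["k1_per_s"],
            k2=rec["k2_per_s"],
            k3=rec["k3_per_s"],
            lam=rec["lambda_per_s"],
        )


@dataclass(frozen=True)
class AbsorbedDose:
    """An organ absorbed dose with full provenance."""

    value: float  # Gy
    voi_label: str
    cycle_id: int
    method_tag: MethodTag

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterDomainError(f"absorbed dose must be >= 0, got {self.value}")
        object.__setattr__(self, "method_tag", MethodTag(self.method_tag))

    def to_record(self) -> dict:
        d = asdict(self)
        d["method_tag"] = self.method_tag.value
        d["value_Gy"] = d.pop("value")
        return d


def evaluate_tdrc(params: TriExpParams, t: float | np.ndarray) -> float | np.ndarray:
    """Dose rate (mGy/s) of the tri-exponential curve at time ``t`` (seconds).

    Vectorized over arrays of times.  Raises on negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterDomainError("time must be >= 0")
    r1, r2, r3 = params.rates
    out = (
        -params.omega1 * np.exp(-r1 * t_arr)
        + params.omega2 * np.exp(-r2 * t_arr)
        + params.omega3 * np.exp(-r3 * t_arr)
    )
    return out if t_arr.ndim else float(out)


def integrate_tdrc(params: TriExpParams) -> float:
    """Absorbed dose in Gy: the closed-form [0, inf) integral of the TDRC."""
    r1, r2, r3 = params.rates
    dose_mgy = -params.omega1 / r1 + params.omega2 / r2 + params.omega3 / r3
    return dose_mgy * MGY_TO_GY


def integrate_tdrc_tail(params: TriExpParams, t_start: float) -> float:
    """Closed-form integral of the TDRC over [t_start, inf), in Gy.

    Used to bound the tail analytically when cross-checking the closed-form
    dose against finite-interval quadrature.
    """
    r1, r2, r3 = params.rates
    tail_mgy = (
        -params.omega1 / r1 * math.exp(-r1 * t_start)
        + params.omega2 / r2 * math.exp(-r2 * t_start)
        + params.omega3 / r3 * math.exp(-r3 * t_start)
    )
    return tail_mgy * MGY_TO_GY


def _check_times(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ParameterDomainError("time must be >= 0")


def decay_correct(
    measurements: Iterable[tuple[float, float]], lam: float
) -> list[tuple[float, float]]:
    """Remove physical decay from (t_seconds, odr) pairs: odr -> odr * e^{+lam t}.

    The correction factor at t = 0 is exactly 1; :func:`decay_uncorrect`
    inverts it to machine precision.
    """
    pairs = [(float(t), float(v)) for t, v in measurements]
    _check_times(np.array([t for t, _ in pairs]))
    return [(t, v * math.exp(lam * t)) for t, v in pairs]


def decay_uncorrect(
    measurements: Iterable[tuple[float, float]], lam: float
) -> list[tuple[float, float]]:
    """Re-apply physical decay: inverse of :func:`decay_correct`."""
    pairs = [(float(t), float(v)) for t, v in measurements]
    _check_times(np.array([t for t, _ in pairs]))
    return [(t, v * math.exp(-lam * t)) for t, v in pairs]
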