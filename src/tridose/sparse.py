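"""Dose estimators for cycles with missing or single SPECT/CT time-points.

Three fallbacks complete the adaptive workflow when the full three-point
schedule is unavailable:

* **M1 (missing time-point)** — a cycle missing one acquisition borrows the
  same slot's organ dose rate from another cycle of the same patient,
  scaled by the ratio of injected activities, and the tri-exponential fit
  proceeds on the completed triple.  The donor's exact acquisition time is
  used.
* **M2 (single time-point, intra-patient)** — a single-point cycle reuses
  the patient's own fitted reference-cycle curve, rescaled so it passes
  through the measured dose rate; the dose scales by the same factor
  (identical pharmacokinetics assumed across cycles).
* **M3 (single time-point, inter-patient)** — when no reference fit exists
  for the patient, a population-average activity-normalized curve is
  rescaled to the measured dose rate instead; validated by leave-one-out.

A missing whole cycle is extrapolated as the mean of the available cycle
doses times the number of missing cycles.

Exactness limits (tested): M1 is exact when the donor's kinetics scaled by
the activity ratio match the missing point; M2 is exact when a cycle is a
positive scalar multiple of the reference cycle; M3 is exact (to grid
interpolation) on a kinetically homogeneous cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .kinetics import (
    HOURS_TO_SECONDS,
    MGY_TO_GY,
    AbsorbedDose,
    MethodTag,
    TriExpParams,
    evaluate_tdrc,
    integrate_tdrc,
)
from .fitting import (
    FitResult,
    InsufficientDataError,
    Slot,
    TimePointMeasurement,
    fit_triexp,
)

__all__ = [
    "CycleRecord",
    "PatientRecord",
    "PopulationTemplate",
    "FallbackUnavailableError",
    "UnusableTimeError",
    "InsufficientCohortError",
    "m1_substitute_odr",
    "m2_stp_intra",
    "build_population_template",
    "m3_stp_inter",
    "extrapolate_missing_cycles",
]

TEMPLATE_GRID_STEP_HOURS = 0.1
TEMPLATE_SPAN_HOURS = 600.0


class FallbackUnavailableError(ValueError):
    """No donor cycle can supply the missing slot."""


class UnusableTimeError(ValueError):
    """The reference curve or template is non-positive/undefined at this time."""


class InsufficientCohortError(ValueError):
    """Too few contributing patients for a population template."""


@dataclass
class CycleRecord:
    """One therapy cycle: injected activity plus per-VOI measurements/fits."""

    cycle_id: int
    injected_activity_mbq: float
    measurements: dict[str, list[TimePointMeasurement]] = field(default_factory=dict)
    fits: dict[str, FitResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be > 0")

    def points(self, voi: str) -> list[TimePointMeasurement]:
        return sorted(self.measurements.get(voi, []), key=lambda p: p.t_hours)

    def slot_point(self, voi: str, slot: Slot) -> Optional[TimePointMeasurement]:
        for p in self.points(voi):
            if p.nominal_slot == slot:
                return p
        return None


@dataclass
class PatientRecord:
    """All cycles of one patient (cycle ids unique)."""

    patient_id: str
    cycles: list[CycleRecord] = field(default_factory=list)
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        ids = [c.cycle_id for c in self.cycles]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cycle ids for patient {self.patient_id}")

    def cycle(self, cycle_id: int) -> CycleRecord:
        for c in self.cycles:
            if c.cycle_id == cycle_id:
                return c
        raise KeyError(f"patient {self.patient_id} has no cycle {cycle_id}")


@dataclass
class PopulationTemplate:
    """Activity-normalized average TDRC of a cohort on a fixed time grid."""

    time_grid_hours: np.ndarray
    mean_curve: np.ndarray  # mGy/s per MBq injected
    n_contributors: int
    voi_label: str
    contributor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time_grid_hours = np.asarray(self.time_grid_hours, dtype=float)
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        if self.time_grid_hours.ndim != 1 or np.any(np.diff(self.time_grid_hours) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.mean_curve.shape != self.time_grid_hours.shape:
            raise ValueError("grid and curve shapes differ")
        if np.any(self.mean_curve < 0):
            raise ValueError("template curve must be >= 0")
        if abs(self.mean_curve[0]) > 1e-12 * max(float(self.mean_curve.max()), 1e-300):
            raise ValueError("template curve must start at 0")

    def value_at(self, t_hours: float) -> float:
        """Linear interpolation on the grid; outside-grid times raise."""
        g = self.time_grid_hours
        if not (g[0] <= t_hours <= g[-1]):
            raise UnusableTimeError(
                f"time {t_hours} h outside template grid [{g[0]}, {g[-1]}] h"
            )
        return float(np.interp(t_hours, g, self.mean_curve))

    @property
    def integral_gy_per_mbq(self) -> float:
        """Trapezoid integral of the template over its grid, Gy per MBq."""
        return float(
            np.trapezoid(self.mean_curve, self.time_grid_hours * HOURS_TO_SECONDS)
            * MGY_TO_GY
        )

    def to_table(self) -> "np.ndarray":
        return np.column_stack([self.time_grid_hours, self.mean_curve])


def m1_substitute_odr(
    target_cycle: CycleRecord,
    donor_cycles: Sequence[CycleRecord],
    voi: str,
    missing_slot: Slot,
    donor_policy: str = "nearest",
    **fit_kwargs,
) -> tuple[TimePointMeasurement, FitResult]:
    """Complete a cycle's missing slot from a donor cycle and refit.

    The donor is the cycle closest in cycle index (``nearest``, earlier
    cycle on ties) or the first following cycle falling back to the first
    preceding one (``next_first``).  The substituted dose rate is the
    donor's, scaled by the ratio of injected activities; the donor's exact
    acquisition time is kept.  Returns the substituted point and the
    tri-exponential fit of the completed triple (tagged M1 downstream).
    """
    own = target_cycle.points(voi)
    if len(own) < 2:
        raise InsufficientDataError(
            f"M1 needs >= 2 real measurements in the target cycle, got {len(own)}"
        )
    candidates = [
        c
        for c in donor_cycles
        if c.cycle_id != target_cycle.cycle_id and c.slot_point(voi, missing_slot)
    ]
    if not candidates:
        raise FallbackUnavailableError(
            f"no donor cycle provides slot {missing_slot.value} for VOI {voi}"
        )
    if donor_policy == "nearest":
        donor = min(
            candidates,
            key=lambda c: (abs(c.cycle_id - target_cycle.cycle_id), c.cycle_id),
        )
    elif donor_policy == "next_first":
        later = [c for c in candidates if c.cycle_id > target_cycle.cycle_id]
        donor = min(later, key=lambda c: c.cycle_id) if later else max(
            candidates, key=lambda c: c.cycle_id
        )
    else:
        raise ValueError(f"unknown donor policy {donor_policy!r}")
    dp = donor.slot_point(voi, missing_slot)
    scale = target_cycle.injected_activity_mbq / donor.injected_activity_mbq
    substituted = TimePointMeasurement(
        t_hours=dp.t_hours,  # the donor's exact acquisition time is used
        odr=dp.odr * scale,
        voi_label=voi,
        cycle_id=target_cycle.cycle_id,
        nominal_slot=missing_slot,
    )
    fit = fit_triexp(own + [substituted], **fit_kwargs)
    return substituted, fit


def m2_stp_intra(
    ref_fit: FitResult,
    ref_dose_gy: float,
    single: TimePointMeasurement,
) -> AbsorbedDose:
    """Single-time-point dose from the patient's own reference-cycle curve.

    The reference TDRC is scaled by the ratio of the measured dose rate to
    the curve value at the measurement time; under the similar-
    pharmacokinetics assumption the absorbed dose scales identically.
    """
    if not ref_fit.converged:
        raise ValueError("M2 requires a converged reference fit")
    if single.t_hours > TEMPLATE_SPAN_HOURS:
        raise UnusableTimeError(
            f"{single.t_hours} h lies beyond the {TEMPLATE_SPAN_HOURS:g} h "
            "support of the fitted curve"
        )
    ref_value = float(evaluate_tdrc(ref_fit.params, single.t_seconds))
    if ref_value <= 0:
        raise UnusableTimeError(
            f"reference curve is {ref_value:g} mGy/s at {single.t_hours} h; "
            "cannot scale"
        )
    scale = single.odr / ref_value
    return AbsorbedDose(
        value=scale * ref_dose_gy,
        voi_label=single.voi_label or "",
        cycle_id=single.cycle_id,
        method_tag=MethodTag.M2,
    )


def build_population_template(
    fits: dict[str, FitResult],
    activities_mbq: dict[str, float],
    voi_label: str,
    leave_out: Optional[str] = None,
    grid_step_hours: float = TEMPLATE_GRID_STEP_HOURS,
    span_hours: float = TEMPLATE_SPAN_HOURS,
) -> PopulationTemplate:
    """Average the cohort's fitted curves, normalized per MBq injected.

    Each contributing patient's fitted TDRC is evaluated on a common
    [0, span] grid, divided by that patient's injected activity, and the
    curves are averaged pointwise.  ``leave_out`` excludes one patient (the
    leave-one-out protocol used to validate M3).
    """
    contributors = sorted(pid for pid in fits if pid != leave_out)
    if not contributors:
        raise InsufficientCohortError("no contributing patients after leave-out")
    grid_h = np.arange(0.0, span_hours + 0.5 * grid_step_hours, grid_step_hours)
    grid_s = grid_h * HOURS_TO_SECONDS
    curves = []
    for pid in contributors:
        act = activities_mbq[pid]
        if act <= 0:
            raise ValueError(f"injected activity for {pid} must be > 0")
        curve = np.asarray(evaluate_tdrc(fits[pid].params, grid_s)) / act
        curves.append(np.clip(curve, 0.0, None))
    mean_curve = np.mean(curves, axis=0)
    return PopulationTemplate(
        time_grid_hours=grid_h,
        mean_curve=mean_curve,
        n_contributors=len(contributors),
        voi_label=voi_label,
        contributor_ids=tuple(contributors),
    )


def m3_stp_inter(
    template: PopulationTemplate,
    measurements: TimePointMeasurement | Sequence[TimePointMeasurement],
) -> AbsorbedDose:
    """Single-time-point dose from a population-average curve.

    The template is scaled so it passes through the measured dose rate at
    the measurement time (linear interpolation on the template grid); the
    dose is that scale times the template's trapezoid integral.  When
    several measurements are supplied, the latest one is used for scaling.
    """
    if isinstance(measurements, TimePointMeasurement):
        single = measurements
    else:
        if not measurements:
            raise InsufficientDataError("M3 needs at least one measurement")
        single = max(measurements, key=lambda p: p.t_hours)
    tmpl_value = template.value_at(single.t_hours)
    if tmpl_value <= 0:
        raise UnusableTimeError(
            f"template is {tmpl_value:g} at {single.t_hours} h; cannot scale"
        )
    scale = single.odr / tmpl_value
    return AbsorbedDose(
        value=scale * template.integral_gy_per_mbq,
        voi_label=single.voi_label or template.voi_label,
        cycle_id=single.cycle_id,
        method_tag=MethodTag.M3,
    )


def extrapolate_missing_cycles(
    doses_available_gy: Sequence[float], n_missing: int
) -> AbsorbedDose:
    """Cumulative dose with missing cycles filled by the mean available dose.

    cumulative = sum(available) + mean(available) * n_missing.
    """
    doses = [float(d) for d in doses_available_gy]
    if not doses:
        raise InsufficientDataError("at least one cycle dose is required")
    if n_missing < 0:
        raise ValueError("n_missing must be >= 0")
    total = sum(doses) + (sum(doses) / len(doses)) * n_missing
    return AbsorbedDose(
        value=total, voi_label="", cycle_id=-1, method_tag=MethodTag.EXTRAPOLATED
    )
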