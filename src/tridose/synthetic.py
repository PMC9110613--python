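"""Virtual cohorts with known ground truth for exercising every estimator.

The generator emulates the kinetic structure of organ time dose-rate
curves after a ~7.4 GBq injection: a fast uptake phase (half-time tens of
minutes), a rapid washout (half-time a few hours) and a long-term
clearance (biological half-time of days), with log-normal inter-patient
parameter heterogeneity, inter-cycle amplitude variability, multiplicative
log-normal measurement noise, and the clinical acquisition schedule (three
points near 1 h / 24 h / 96 or 144 h at the first cycle, a single 24 h
point afterwards, with configurable missingness).

The washout phase is tied to the clearance phase through population-level
ratios (rate ratio 10, amplitude ratio 2) — the same structural constants
the three-point fit assumes; inter-patient and inter-cycle heterogeneity
enters through the clearance scale, the uptake rate, the amplitudes and
the injected activities.

Every generated measurement derives from an exact tri-exponential ground
truth whose closed-form dose is stored alongside, so estimator errors are
measured against known values, and everything is reproducible from the
spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .kinetics import TriExpParams, evaluate_tdrc, integrate_tdrc, lu177_lambda
from .fitting import K2_OVER_K3, OMEGA2_OVER_OMEGA3, Slot, TimePointMeasurement
from .image_dose import ScalarVolume, VoiMask
from .sparse import CycleRecord, PatientRecord

__all__ = [
    "OrganKinetics",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_phantom",
    "make_conserved_kinetics_patient",
    "DEFAULT_ORGAN_SCALES",
]

#: Median terminal-phase amplitude Omega3 (mGy/s) per VOI, chosen so that
#: per-cycle organ doses land in the clinically reported magnitude bands
#: (kidneys ~3 Gy/cycle, liver/spleen ~4-5 Gy/cycle, vertebral bone-marrow
#: surrogates ~0.3 Gy/cycle).
DEFAULT_ORGAN_SCALES: dict[str, float] = {
    "LK": 9.4e-3,
    "RK": 9.4e-3,
    "L": 1.35e-2,
    "S": 1.35e-2,
    "L2L4": 9.4e-4,
    "L1L5": 9.4e-4,
    "T9L5": 9.4e-4,
}


@dataclass(frozen=True)
class OrganKinetics:
    """Log-normal inter-patient distributions of the kinetic parameters.

    Medians and log-space sigmas; rates in 1/s, amplitudes in mGy/s.
    The washout phase is derived as k2 = k2_over_k3 * k3 and
    Omega2 = omega2_over_omega3 * Omega3.
    """

    k1_median: float = 3.5e-4  # uptake half-time ~33 min
    k1_sigma: float = 0.35
    k3_median: float = 2.7e-6  # clearance half-time ~71 h biological
    k3_sigma: float = 0.26
    omega3_sigma: float = 0.4
    k2_over_k3: float = K2_OVER_K3
    omega2_over_omega3: float = OMEGA2_OVER_OMEGA3


@dataclass(frozen=True)
class CohortSpec:
    """Everything that defines a virtual cohort; the seed fixes it all."""

    n_patients: int = 13
    vois: tuple[str, ...] = ("LK", "RK", "L", "S", "L2L4")
    kinetics: OrganKinetics = field(default_factory=OrganKinetics)
    injected_activity_mean_mbq: float = 6832.0
    injected_activity_sd_mbq: float = 158.0
    n_cycles: int = 4
    full_schedule_cycles: tuple[int, ...] = (1,)
    late_slot_hours: tuple[float, ...] = (96.0, 144.0)  # alternates per patient
    early_slot_hours: float = 1.0
    mid_slot_hours: float = 24.0
    time_jitter_frac: float = 0.15
    inter_cycle_amplitude_cv: float = 0.10
    inter_cycle_k3_cv: float = 0.0
    noise_cv: float = 0.05
    missing: tuple[tuple[str, int, str], ...] = ()  # (patient_id, cycle_id, slot)
    cohort_id: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if min(self.inter_cycle_amplitude_cv, self.noise_cv,
               self.inter_cycle_k3_cv) < 0:
            raise ValueError("CVs must be >= 0")
        if not self.vois or self.n_cycles < 1:
            raise ValueError("need at least one VOI and one cycle")


@dataclass
class GroundTruth:
    """True parameters and closed-form doses per (patient, cycle, VOI)."""

    params: dict[tuple[str, int, str], TriExpParams] = field(default_factory=dict)
    doses_gy: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def record(self, pid: str, cycle: int, voi: str, p: TriExpParams) -> None:
        self.params[(pid, cycle, voi)] = p
        self.doses_gy[(pid, cycle, voi)] = integrate_tdrc(p)

    def to_records(self) -> list[dict]:
        return [
            {
                "patient_id": pid,
                "cycle_id": cyc,
                "voi": voi,
                "true_dose_Gy": self.doses_gy[(pid, cyc, voi)],
                **p.to_record(),
            }
            for (pid, cyc, voi), p in self.params.items()
        ]


def _cv_to_sigma(cv: float) -> float:
    """Log-space sigma of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _draw_patient_params(
    rng: np.random.Generator, kin: OrganKinetics, omega3_scale: float, lam: float
) -> TriExpParams:
    for _ in range(100):
        k3 = kin.k3_median * rng.lognormal(0.0, kin.k3_sigma)
        k2 = kin.k2_over_k3 * k3
        k1 = kin.k1_median * rng.lognormal(0.0, kin.k1_sigma)
        om3 = omega3_scale * rng.lognormal(0.0, kin.omega3_sigma)
        om2 = kin.omega2_over_omega3 * om3
        if k1 > k2 > k3 >= 0:
            return TriExpParams(om2 + om3, om2, om3, k1, k2, k3, lam)
    raise ValueError(
        "kinetic distributions violate the rate ordering k1 > k2 > k3; "
        "check the spec's medians and sigmas"
    )


def generate_cohort(
    spec: CohortSpec, lam: Optional[float] = None
) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a reproducible virtual cohort and its ground truth.

    Per patient, base organ kinetics are drawn from the spec distributions;
    per cycle, the amplitudes are jittered by the inter-cycle CV (a common
    factor, preserving the zero-at-origin constraint) and scaled by the
    cycle's injected activity relative to the first; measurements are exact
    curve values at schedule times (each jittered around its nominal slot)
    times multiplicative log-normal noise; missingness rules remove the
    listed (patient, cycle, slot) acquisitions.
    """
    if lam is None:
        lam = lu177_lambda()
    rng = np.random.default_rng(spec.seed)
    amp_sigma = _cv_to_sigma(spec.inter_cycle_amplitude_cv)
    k3_sigma = _cv_to_sigma(spec.inter_cycle_k3_cv)
    noise_sigma = _cv_to_sigma(spec.noise_cv)
    missing = set(spec.missing)
    patients: list[PatientRecord] = []
    truth = GroundTruth()
    for ip in range(spec.n_patients):
        pid = f"P{ip + 1:02d}"
        late_nominal = spec.late_slot_hours[ip % len(spec.late_slot_hours)]
        base = {
            voi: _draw_patient_params(
                rng, spec.kinetics, DEFAULT_ORGAN_SCALES.get(voi, 9.4e-3), lam
            )
            for voi in spec.vois
        }
        act1: Optional[float] = None
        cycles = []
        for cyc in range(1, spec.n_cycles + 1):
            activity = float(
                max(
                    rng.normal(spec.injected_activity_mean_mbq,
                               spec.injected_activity_sd_mbq),
                    1.0,
                )
            )
            if act1 is None:
                act1 = activity
            if cyc in spec.full_schedule_cycles:
                slots = [
                    (Slot.EARLY, spec.early_slot_hours),
                    (Slot.H24, spec.mid_slot_hours),
                    (Slot.LATE, late_nominal),
                ]
            else:
                slots = [(Slot.H24, spec.mid_slot_hours)]
            record = CycleRecord(cycle_id=cyc, injected_activity_mbq=activity)
            amp_factor = (activity / act1) * (
                rng.lognormal(0.0, amp_sigma) if amp_sigma > 0 else 1.0
            )
            for voi in spec.vois:
                p0 = base[voi]
                k3_c = p0.k3 * (rng.lognormal(0.0, k3_sigma) if k3_sigma > 0 else 1.0)
                k2_c = spec.kinetics.k2_over_k3 * k3_c
                if not p0.k1 > k2_c:
                    k2_c = p0.k1 * 0.5
                    k3_c = k2_c / spec.kinetics.k2_over_k3
                p = TriExpParams(
                    p0.omega1 * amp_factor,
                    p0.omega2 * amp_factor,
                    p0.omega3 * amp_factor,
                    p0.k1,
                    k2_c,
                    k3_c,
                    lam,
                )
                truth.record(pid, cyc, voi, p)
                points = []
                for slot, nominal in slots:
                    if (pid, cyc, slot.value) in missing:
                        continue
                    t_h = nominal * float(
                        rng.uniform(1.0 - spec.time_jitter_frac,
                                    1.0 + spec.time_jitter_frac)
                    )
                    odr = float(evaluate_tdrc(p, t_h * 3600.0))
                    if noise_sigma > 0:
                        odr *= float(rng.lognormal(0.0, noise_sigma))
                    points.append(
                        TimePointMeasurement(
                            t_hours=t_h, odr=odr, voi_label=voi,
                            cycle_id=cyc, nominal_slot=slot,
                        )
                    )
                record.measurements[voi] = points
            cycles.append(record)
        patients.append(
            PatientRecord(patient_id=pid, cycles=cycles, cohort_id=spec.cohort_id)
        )
    return patients, truth


def make_conserved_kinetics_patient(
    base_params: dict[str, TriExpParams],
    cycle_scales: Sequence[float],
    activities_mbq: Optional[Sequence[float]] = None,
    schedule_hours: Sequence[float] = (1.0, 24.0, 96.0),
    patient_id: str = "SYN",
    cohort_id: str = "cohort",
) -> tuple[PatientRecord, GroundTruth]:
    """A patient whose cycle N curve is exactly scale_N times the cycle-1 curve.

    Noiseless measurements lie on the true curves; the ground-truth dose
    scales identically.  When ``activities_mbq`` is omitted, injected
    activities are proportional to the cycle scales (activity-conserved
    kinetics, the exactness limit of the M1 substitution); any positive
    scales give the exactness limit of M2.
    """
    scales = [float(s) for s in cycle_scales]
    if any(s <= 0 for s in scales):
        raise ValueError("cycle scales must be > 0")
    if activities_mbq is None:
        activities_mbq = [7400.0 * s for s in scales]
    slots = {0: Slot.EARLY, 1: Slot.H24}
    truth = GroundTruth()
    cycles = []
    for i, (scale, act) in enumerate(zip(scales, activities_mbq), start=1):
        record = CycleRecord(cycle_id=i, injected_activity_mbq=float(act))
        for voi, p0 in base_params.items():
            p = TriExpParams(
                p0.omega1 * scale, p0.omega2 * scale, p0.omega3 * scale,
                p0.k1, p0.k2, p0.k3, p0.lam,
            )
            truth.record(patient_id, i, voi, p)
            record.measurements[voi] = [
                TimePointMeasurement(
                    t_hours=float(t),
                    odr=float(evaluate_tdrc(p, float(t) * 3600.0)),
                    voi_label=voi,
                    cycle_id=i,
                    nominal_slot=slots.get(j, Slot.LATE),
                )
                for j, t in enumerate(schedule_hours)
            ]
        cycles.append(record)
    return (
        PatientRecord(patient_id=patient_id, cycles=cycles, cohort_id=cohort_id),
        truth,
    )


def generate_phantom(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    organs: Sequence[tuple[str, tuple[float, float, float], tuple[float, float, float], float]],
    unit: str = "mGy/s",
) -> tuple[ScalarVolume, list[VoiMask], dict[str, float]]:
    """Voxelized ellipsoid phantom with uniform per-organ values.

    ``organs`` is a sequence of (label, center_mm, semi_axes_mm, value);
    earlier organs take priority where ellipsoids overlap.  Returns the
    value volume, one mask per organ and the analytic per-organ mean (the
    assigned value), against which VOI statistics can be checked exactly.
    Organs whose bounding box leaves the grid raise.
    """
    shape = tuple(int(s) for s in shape)
    vol = np.zeros(shape, dtype=float)
    claimed = np.zeros(shape, dtype=bool)
    masks: list[VoiMask] = []
    analytic: dict[str, float] = {}
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing_mm)), indexing="ij"
    )
    extent = [n * s for n, s in zip(shape, spacing_mm)]
    for label, center, axes, value in organs:
        if any(a <= 0 for a in axes):
            raise ValueError(f"organ {label!r} has a degenerate (zero) axis")
        if any(c - a < 0 or c + a > e for c, a, e in zip(center, axes, extent)):
            raise ValueError(f"organ {label!r} leaves the grid")
        inside = (
            ((zz - center[0]) / axes[0]) ** 2
            + ((yy - center[1]) / axes[1]) ** 2
            + ((xx - center[2]) / axes[2]) ** 2
        ) <= 1.0
        inside &= ~claimed  # earlier organs take priority
        if not inside.any():
            raise ValueError(f"organ {label!r} covers no voxel at this spacing")
        claimed |= inside
        vol[inside] = value
        masks.append(
            VoiMask(values=inside, label=label, spacing=spacing_mm)
        )
        analytic[label] = float(value)
    return (
        ScalarVolume(values=vol, spacing=spacing_mm, unit=unit),
        masks,
        analytic,
    )
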