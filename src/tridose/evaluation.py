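"""Comparison statistics for the dosimetry methods.

Percentage dose difference (PDD) against the tri-exponential reference,
inter-cycle variation coefficients of activity-scaled organ dose rates,
leave-one-out error distributions for the single-time-point estimators,
and [minimum; median; maximum; mean] summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .fitting import FitResult, Slot, TimePointMeasurement, fit_triexp
from .kinetics import integrate_tdrc
from .sparse import (
    PatientRecord,
    build_population_template,
    m2_stp_intra,
    m3_stp_inter,
)

__all__ = [
    "MethodComparison",
    "pdd",
    "odr_variation_coefficient",
    "summarize",
    "loocv_evaluate",
]

log = logging.getLogger("tridose.evaluation")


def pdd(d_method_gy: float, d_ref_gy: float) -> float:
    """Signed percentage dose difference: 100 * (method - reference) / reference."""
    if d_ref_gy <= 0:
        raise ValueError(f"reference dose must be > 0, got {d_ref_gy}")
    return 100.0 * (d_method_gy - d_ref_gy) / d_ref_gy


def summarize(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, median, max, mean, sd) of a non-empty sample; sd uses n-1.

    With a single value the sd is reported as NaN (undefined).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return (
        float(arr.min()),
        float(np.median(arr)),
        float(arr.max()),
        float(arr.mean()),
        sd,
    )


def odr_variation_coefficient(
    odrs: Sequence[float], activities_mbq: Sequence[float]
) -> float:
    """Inter-cycle variability (%) of dose rates scaled to the first activity.

    Each cycle's dose rate is rescaled by (first activity / its activity);
    the coefficient of variation (sample sd over mean, in percent) of the
    scaled values then measures kinetic — not injection — variability.
    """
    odrs = np.asarray(list(odrs), dtype=float)
    acts = np.asarray(list(activities_mbq), dtype=float)
    if odrs.size < 2 or odrs.shape != acts.shape:
        raise ValueError("need >= 2 cycles with matching activities")
    if np.any(acts <= 0):
        raise ValueError("activities must be > 0")
    scaled = odrs * (acts[0] / acts)
    mean = scaled.mean()
    if mean == 0:
        raise ValueError("CV undefined: zero mean of scaled dose rates")
    return 100.0 * float(np.std(scaled, ddof=1)) / float(mean)


@dataclass
class MethodComparison:
    """PDD distribution of one method for one VOI and time slot."""

    voi_label: str
    time_slot: str
    method: str
    pdd_values: list[float] = field(default_factory=list)

    @property
    def summary(self) -> tuple[float, float, float, float, float]:
        return summarize(self.pdd_values)

    def to_record(self) -> dict:
        mn, med, mx, mean, sd = self.summary
        return {
            "voi": self.voi_label,
            "slot": self.time_slot,
            "method": self.method,
            "n": len(self.pdd_values),
            "min_pct": mn,
            "median_pct": med,
            "max_pct": mx,
            "mean_pct": mean,
            "sd_pct": sd,
        }


def _reference_fit(
    patient: PatientRecord, cycle_id: int, voi: str, **fit_kwargs
) -> Optional[FitResult]:
    cyc = patient.cycle(cycle_id)
    if voi in cyc.fits:
        return cyc.fits[voi]
    pts = cyc.points(voi)
    if len({p.t_hours for p in pts}) < 3:
        return None
    try:
        fit = fit_triexp(pts, **fit_kwargs)
    except Exception as exc:  # noqa: BLE001 - skipped patients are logged
        log.info("reference fit failed for %s cycle %d %s: %s",
                 patient.patient_id, cycle_id, voi, exc)
        return None
    cyc.fits[voi] = fit
    return fit


def loocv_evaluate(
    cohort: Sequence[PatientRecord],
    estimator: str,
    vois: Sequence[str],
    slots: Sequence[Slot] = (Slot.EARLY, Slot.H24, Slot.LATE),
    eval_cycle: int = 1,
    ref_cycle: int = 1,
    **fit_kwargs,
) -> list[MethodComparison]:
    """Leave-one-out error distributions for the single-point estimators.

    For every patient with a full three-point reference fit at
    ``eval_cycle``, the reference dose is the fit's integral; the estimator
    (``"M2"`` or ``"M3"``) then re-estimates that dose from each slot's
    single measurement alone.  For M3 the population template is rebuilt
    for each patient excluding that patient, independently per cohort id,
    so no patient ever contributes to its own template.  For M2 the
    patient's own ``ref_cycle`` fit is the reference curve (with
    ``ref_cycle == eval_cycle`` this checks self-consistency; across cycles
    it measures the similar-pharmacokinetics assumption).  Patients without
    a reference fit are skipped with a logged reason.
    """
    if estimator not in ("M2", "M3"):
        raise ValueError("estimator must be 'M2' or 'M3'")
    comparisons = {
        (voi, slot.value): MethodComparison(voi, slot.value, estimator)
        for voi in vois
        for slot in slots
    }
    for voi in vois:
        fits: dict[str, FitResult] = {}
        doses: dict[str, float] = {}
        acts: dict[str, float] = {}
        cohort_of: dict[str, str] = {}
        for patient in cohort:
            fit = _reference_fit(patient, eval_cycle, voi, **fit_kwargs)
            if fit is None:
                log.info("skipping %s / %s: no 3-point reference fit",
                         patient.patient_id, voi)
                continue
            fits[patient.patient_id] = fit
            doses[patient.patient_id] = integrate_tdrc(fit.params)
            acts[patient.patient_id] = patient.cycle(eval_cycle).injected_activity_mbq
            cohort_of[patient.patient_id] = patient.cohort_id
        for patient in cohort:
            pid = patient.patient_id
            if pid not in fits:
                continue
            ref_dose = doses[pid]
            cyc = patient.cycle(eval_cycle)
            for slot in slots:
                point = cyc.slot_point(voi, slot)
                if point is None:
                    continue
                if estimator == "M2":
                    ref_fit = _reference_fit(patient, ref_cycle, voi, **fit_kwargs)
                    if ref_fit is None:
                        continue
                    ref_cycle_dose = integrate_tdrc(ref_fit.params)
                    est = m2_stp_intra(ref_fit, ref_cycle_dose, point)
                else:
                    peer_fits = {
                        q: f for q, f in fits.items() if cohort_of[q] == cohort_of[pid]
                    }
                    template = build_population_template(
                        peer_fits, acts, voi, leave_out=pid
                    )
                    assert pid not in template.contributor_ids
                    est = m3_stp_inter(template, point)
                comparisons[(voi, slot.value)].pdd_values.append(
                    pdd(est.value, ref_dose)
                )
    return [c for c in comparisons.values() if c.pdd_values]
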