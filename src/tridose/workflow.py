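"""The adaptive dose-estimation workflow.

Routing per (patient, cycle, VOI), in priority order:

1. three or more time-points -> the reference tri-exponential fit;
2. exactly one slot of the full schedule missing, a donor cycle has it ->
   M1 (substitute the donor's dose rate, scaled by activity, and refit);
3. a single point and a fitted reference cycle for this patient -> M2;
4. a single point and a population template from the rest of the cohort ->
   M3;
5. otherwise the cycle is left unestimated (logged).

Every routing decision is logged and every emitted dose carries its method
tag plus, where applicable, the donor cycle or template provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .evaluation import pdd
from .fitting import (
    FitResult,
    InsufficientDataError,
    NonConvergenceError,
    Slot,
    fit_triexp,
)
from .io import WorkflowConfig
from .kinetics import MethodTag, integrate_tdrc
from .sparse import (
    FallbackUnavailableError,
    PatientRecord,
    PopulationTemplate,
    UnusableTimeError,
    build_population_template,
    m1_substitute_odr,
    m2_stp_intra,
    m3_stp_inter,
)

__all__ = ["DoseRow", "run_workflow", "reference_cycle_for", "build_cohort_templates"]

log = logging.getLogger("tridose.workflow")

FULL_SCHEDULE = (Slot.EARLY, Slot.H24, Slot.LATE)

DOSE_COLUMNS = [
    "cohort_id",
    "patient_id",
    "cycle_id",
    "voi",
    "dose_Gy",
    "method_tag",
    "provenance",
]


def _fit_kwargs(config: WorkflowConfig) -> dict:
    return {
        "lam": config.lam,
        "tol_first_point": config.tol_first_point_mgy_per_s,
        "seed": config.seed,
        "k2_over_k3": config.k2_over_k3,
        "omega2_over_omega3": config.omega2_over_omega3,
    }


def reference_cycle_for(
    patient: PatientRecord, voi: str, config: WorkflowConfig
) -> Optional[int]:
    """The configured reference cycle, or the earliest with >= 3 points."""
    if config.reference_cycle > 0:
        return config.reference_cycle
    for cyc in sorted(patient.cycles, key=lambda c: c.cycle_id):
        if len({p.t_hours for p in cyc.points(voi)}) >= 3:
            return cyc.cycle_id
    return None


def _ensure_reference_fit(
    patient: PatientRecord, voi: str, config: WorkflowConfig
) -> Optional[tuple[int, FitResult]]:
    ref_id = reference_cycle_for(patient, voi, config)
    if ref_id is None:
        return None
    cyc = patient.cycle(ref_id)
    if voi not in cyc.fits:
        pts = cyc.points(voi)
        if len({p.t_hours for p in pts}) < 3:
            return None
        try:
            cyc.fits[voi] = fit_triexp(pts, **_fit_kwargs(config))
        except (NonConvergenceError, InsufficientDataError) as exc:
            log.warning("reference fit failed: %s %s cycle %d: %s",
                        patient.patient_id, voi, ref_id, exc)
            return None
    return ref_id, cyc.fits[voi]


def build_cohort_templates(
    patients: Sequence[PatientRecord],
    vois: Sequence[str],
    config: WorkflowConfig,
    leave_out: Optional[str] = None,
) -> dict[str, PopulationTemplate]:
    """Per-VOI population templates from all available reference fits."""
    templates: dict[str, PopulationTemplate] = {}
    for voi in vois:
        fits: dict[str, FitResult] = {}
        acts: dict[str, float] = {}
        for pat in patients:
            ref = _ensure_reference_fit(pat, voi, config)
            if ref is None:
                continue
            ref_id, fit = ref
            fits[pat.patient_id] = fit
            acts[pat.patient_id] = pat.cycle(ref_id).injected_activity_mbq
        if len(fits) - (1 if leave_out in fits else 0) >= 1:
            templates[voi] = build_population_template(
                fits,
                acts,
                voi,
                leave_out=leave_out,
                grid_step_hours=config.template_grid_step_hours,
                span_hours=config.template_span_hours,
            )
    return templates


def run_workflow(
    patients: Sequence[PatientRecord],
    config: Optional[WorkflowConfig] = None,
    templates: Optional[dict[str, PopulationTemplate]] = None,
) -> pd.DataFrame:
    """Estimate one absorbed dose per (patient, cycle, VOI).

    Returns a dose table with method tags and provenance.  Templates for M3
    are built from the supplied cohort when not given explicitly; each
    patient's own template always excludes that patient.
    """
    config = config or WorkflowConfig()
    vois = sorted({v for p in patients for c in p.cycles for v in c.measurements})
    rows = []
    for pat in patients:
        for voi in vois:
            ref = _ensure_reference_fit(pat, voi, config)
            for cyc in sorted(pat.cycles, key=lambda c: c.cycle_id):
                pts = cyc.points(voi)
                if not pts:
                    continue
                tag, dose, provenance = None, None, ""
                if len({p.t_hours for p in pts}) >= 3:
                    try:
                        if voi not in cyc.fits:
                            cyc.fits[voi] = fit_triexp(pts, **_fit_kwargs(config))
                        fit = cyc.fits[voi]
                        tag = MethodTag.TRIEXP_REF
                        dose = integrate_tdrc(fit.params)
                        provenance = f"fit:cycle{cyc.cycle_id}"
                        log.info("%s %s cycle %d: reference tri-exponential fit",
                                 pat.patient_id, voi, cyc.cycle_id)
                    except NonConvergenceError as exc:
                        log.warning("%s %s cycle %d: fit failed (%s)",
                                    pat.patient_id, voi, cyc.cycle_id, exc)
                if tag is None and len(pts) == 2:
                    present = {p.nominal_slot for p in pts}
                    gap = [s for s in FULL_SCHEDULE if s not in present]
                    if len(gap) == 1:
                        try:
                            _, fit = m1_substitute_odr(
                                cyc,
                                [c for c in pat.cycles if c.cycle_id != cyc.cycle_id],
                                voi,
                                gap[0],
                                donor_policy=config.donor_policy,
                                **_fit_kwargs(config),
                            )
                            tag = MethodTag.M1
                            dose = integrate_tdrc(fit.params)
                            provenance = f"donor-slot:{gap[0].value}"
                            log.info("%s %s cycle %d: M1 (missing %s substituted)",
                                     pat.patient_id, voi, cyc.cycle_id, gap[0].value)
                        except (FallbackUnavailableError, NonConvergenceError,
                                InsufficientDataError) as exc:
                            log.info("%s %s cycle %d: M1 unavailable (%s)",
                                     pat.patient_id, voi, cyc.cycle_id, exc)
                if tag is None and ref is not None and cyc.cycle_id != ref[0]:
                    ref_id, ref_fit = ref
                    try:
                        est = m2_stp_intra(
                            ref_fit, integrate_tdrc(ref_fit.params),
                            max(pts, key=lambda p: p.t_hours),
                        )
                        tag, dose = MethodTag.M2, est.value
                        provenance = f"ref-cycle:{ref_id}"
                        log.info("%s %s cycle %d: M2 (intra-patient scaling)",
                                 pat.patient_id, voi, cyc.cycle_id)
                    except UnusableTimeError as exc:
                        log.info("%s %s cycle %d: M2 unusable (%s)",
                                 pat.patient_id, voi, cyc.cycle_id, exc)
                if tag is None:
                    tmpl_map = templates
                    if tmpl_map is None:
                        tmpl_map = build_cohort_templates(
                            patients, [voi], config, leave_out=pat.patient_id
                        )
                    tmpl = tmpl_map.get(voi)
                    if tmpl is not None:
                        try:
                            est = m3_stp_inter(tmpl, pts)
                            tag, dose = MethodTag.M3, est.value
                            provenance = f"template:n={tmpl.n_contributors}"
                            log.info("%s %s cycle %d: M3 (population template)",
                                     pat.patient_id, voi, cyc.cycle_id)
                        except UnusableTimeError as exc:
                            log.info("%s %s cycle %d: M3 unusable (%s)",
                                     pat.patient_id, voi, cyc.cycle_id, exc)
                if tag is None:
                    log.warning("%s %s cycle %d: no estimator applicable",
                                pat.patient_id, voi, cyc.cycle_id)
                    continue
                rows.append(
                    {
                        "cohort_id": pat.cohort_id,
                        "patient_id": pat.patient_id,
                        "cycle_id": cyc.cycle_id,
                        "voi": voi,
                        "dose_Gy": dose,
                        "method_tag": tag.value,
                        "provenance": provenance,
                    }
                )
    return pd.DataFrame(rows, columns=DOSE_COLUMNS)
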