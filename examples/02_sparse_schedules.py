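"""Estimate doses when acquisitions are missing: M1, M2 and M3 fallbacks.

A patient with conserved kinetics across cycles (each cycle a scalar
multiple of cycle 1) illustrates the analytic exactness limits of the
three sparse-schedule estimators.
"""

import numpy as np

from tridose import (
    TimePointMeasurement,
    TriExpParams,
    build_population_template,
    evaluate_tdrc,
    integrate_tdrc,
    lu177_lambda,
    m1_substitute_odr,
    m2_stp_intra,
    m3_stp_inter,
)
from tridose.fitting import FitResult, Slot
from tridose.sparse import CycleRecord
from tridose.synthetic import make_conserved_kinetics_patient

lam = lu177_lambda()
base = TriExpParams(2.4e-2, 1.6e-2, 8e-3, 3.5e-4, 2.7e-5, 2.7e-6, lam)
dose1 = integrate_tdrc(base)

# --- M1: one slot missing, borrowed from another cycle --------------------
patient, truth = make_conserved_kinetics_patient({"LK": base}, [1.0, 0.8])
full_cycle2 = patient.cycle(2)
target = CycleRecord(cycle_id=2,
                     injected_activity_mbq=full_cycle2.injected_activity_mbq)
target.measurements["LK"] = [
    p for p in full_cycle2.points("LK") if p.nominal_slot != Slot.H24
]
substituted, m1_fit = m1_substitute_odr(
    target, [patient.cycle(1)], "LK", Slot.H24, lam=lam, seed=0
)
print(f"M1 substituted 24 h ODR : {substituted.odr:.4e} mGy/s "
      f"(donor scaled by activity ratio)")
print(f"M1 dose                 : {integrate_tdrc(m1_fit.params):.4f} Gy  "
      f"(truth {truth.doses_gy[('SYN', 2, 'LK')]:.4f} Gy)")

# --- M2: single point, the patient's own reference curve ------------------
ref_fit = FitResult(params=base, residuals=np.zeros(3),
                    first_point_gap=0.0, converged=True)
odr_24 = 0.8 * float(evaluate_tdrc(base, 24.0 * 3600.0))
m2 = m2_stp_intra(ref_fit, dose1,
                  TimePointMeasurement(t_hours=24.0, odr=odr_24, cycle_id=3))
print(f"\nM2 dose from one 24 h point : {m2.value:.4f} Gy "
      f"(cycle at 0.8 x reference kinetics -> truth {0.8 * dose1:.4f} Gy)")

# --- M3: single point, population-average curve ---------------------------
fits = {f"P{i}": ref_fit for i in range(4)}
acts = {f"P{i}": 7400.0 for i in range(4)}
template = build_population_template(fits, acts, "LK", leave_out="P0")
m3 = m3_stp_inter(template,
                  TimePointMeasurement(t_hours=24.0, odr=odr_24, cycle_id=3))
print(f"M3 dose from the same point : {m3.value:.4f} Gy "
      f"({template.n_contributors}-patient template, leave-one-out)")
print("\nOn a homogeneous cohort both single-point estimators reproduce the")
print("reference dose; their errors grow with inter-cycle/-patient divergence.")
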