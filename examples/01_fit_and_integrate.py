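"""Fit a three-point organ dose-rate curve and integrate it to absorbed dose.

A kidney-like organ is sampled at the clinical schedule (1 h, 24 h, 96 h
post-injection); the tri-exponential fit reconstructs the full time
dose-rate curve and its closed-form time integral is the absorbed dose.
"""

from tridose import (
    TimePointMeasurement,
    TriExpParams,
    evaluate_tdrc,
    fit_triexp,
    integrate_tdrc,
    lu177_lambda,
)
from tridose.fitting import Slot

lam = lu177_lambda()
truth = TriExpParams(omega1=2.4e-2, omega2=1.6e-2, omega3=8e-3,
                     k1=3.5e-4, k2=2.7e-5, k3=2.7e-6, lam=lam)

points = [
    TimePointMeasurement(t_hours=t, odr=float(evaluate_tdrc(truth, t * 3600.0)),
                         nominal_slot=s)
    for t, s in zip((1.0, 24.0, 96.0), (Slot.EARLY, Slot.H24, Slot.LATE))
]
for p in points:
    print(f"measured ODR at {p.t_hours:6.1f} h : {p.odr:.4e} mGy/s")

fit = fit_triexp(points, lam=lam, seed=0)
print(f"\nconverged: {fit.converged}  "
      f"(first-point gap {fit.first_point_gap:.1e} mGy/s)")
print(f"fitted dose     : {fit.dose_gy:.4f} Gy")
print(f"ground truth    : {integrate_tdrc(truth):.4f} Gy")
print("\nThe fitted dose is the [0, inf) integral of the reconstructed curve;")
print("with noiseless measurements it matches the generating kinetics.")
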