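# Methods

## The time dose-rate curve model

After an injection of a ¹⁷⁷Lu-labelled radiopharmaceutical, the mean dose
rate of an organ (its *organ dose rate*, ODR, in mGy/s) follows three
kinetic phases: a fast uptake, a rapid washout, and a long-term clearance.
`tridose` models the resulting time dose-rate curve (TDRC) as

```
TDRC(t) = -Ω₁ e^{-(λ+k₁)t} + Ω₂ e^{-(λ+k₂)t} + Ω₃ e^{-(λ+k₃)t}
```

with amplitudes Ωᵢ ≥ 0 (mGy/s), biological rate constants
k₁ > k₂ > k₃ ≥ 0 (1/s) and λ the physical decay constant of ¹⁷⁷Lu.  The
negative first term produces the uptake phase; the constraint
Ω₁ = Ω₂ + Ω₃ makes the curve exactly zero at the moment of injection.
Because the curve is a dose rate (not an activity), cross-dose between
organs is already contained in the measured values.

The organ absorbed dose is the closed-form time integral over [0, ∞):

```
D [Gy] = ( -Ω₁/(λ+k₁) + Ω₂/(λ+k₂) + Ω₃/(λ+k₃) ) / 1000
```

λ defaults to ln 2 / T½ with T½ = 6.6443 d (evaluated nuclear-data value)
and is overridable everywhere a decay constant is accepted.  External I/O
uses hours and mGy/s; all internal computation is in seconds; doses are
reported in Gy.  This single conversion boundary is tested.

## Fitting three time-points

The clinical schedule provides three acquisitions in the reference cycle
(≈1 h, 24 h, and 96 h or 144 h post-injection).  Three points cannot
identify the five free parameters of the zero-at-origin model: the rapid
washout phase is essentially over between the first and second
acquisitions, so its rate and amplitude are structurally unidentifiable
from the data alone.  The fit therefore ties the washout phase to the
clearance phase through two population-level constants,

* rate ratio `k2_over_k3` = 10 (washout one decade faster than clearance),
* amplitude ratio `omega2_over_omega3` = 2,

both configurable.  The remaining free parameters (Ω₃, k₃, k₁) are exactly
identified by three measurements.  The fit runs in two alternating stages:

1. **Clearance stage.**  Measurements are decay-corrected
   (odr → odr·e^{+λt}); (Ω₃, k₃) are estimated by bounded nonlinear least
   squares (`scipy.optimize.least_squares`) against the second and later
   points plus a zero-valued pseudo-point at 600 h — the boundary
   condition that the dose rate has returned to zero well after the
   cycle.  The pseudo-point residual is evaluated on the *physical* scale
   (the decay factor re-applied), because the boundary condition is a
   statement about the physical dose rate; weighting it on the
   decay-corrected scale would inflate its influence ~14-fold and
   measurably bias slow-clearance fits.
2. **Uptake stage.**  With the clearance fixed and Ω₁ eliminated by the
   zero-at-origin constraint, the first-point gap
   g(k₁) = TDRC(t₁; k₁) − odr₁ is strictly increasing in k₁, and a
   guarded Newton/bisection descent drives |g| below a tolerance of
   1e-5 mGy/s (configurable) on the bracket (k₂, k₁ᵐᵃˣ].

The stages iterate to a fixed point (the uptake term's small residue at
the later points is fed back into stage 1).  A seeded multi-start over the
clearance initialization — terminal log-slope of the decay-corrected data
plus a coarse deterministic grid and log-normal jitters — makes the result
bitwise reproducible; the lowest-cost start wins.

Degenerate and adverse inputs: plateau-like data (non-decaying terminal
slope) trigger a warning; schedules without a point at ≥48 h warn that
the clearance rate is poorly constrained; noisy first points lying above
the curve that the base amplitude ratio allows trigger a bounded
escalation of the ratio (2×, 4×), recorded in the result's messages; a
fitted curve still above 1e-3 of the peak measurement at 600 h (very slow
clearance) is likewise reported rather than forced down.  A fit that
cannot reach the first-point tolerance raises a non-convergence error
carrying the best-so-far result, and the workflow falls back to the
sparse-schedule estimators.

A two-point mono-exponential fit (μ = ln(odr₁/odr₂)/(t₂−t₁),
D = odr₁·e^{μt₁}/μ) is provided for comparison studies only; it raises on
non-decaying pairs, whose extrapolated dose is unbounded.

## Sparse-schedule estimators

* **M1 (missing time-point).**  A cycle missing one of its three slots
  borrows that slot's ODR from the cycle closest in index (earlier cycle
  on ties; a next-cycle-first policy is available), scaled by the ratio of
  injected activities, keeping the donor's exact acquisition time; the
  tri-exponential fit then proceeds normally.  Exact when cycle kinetics
  scale with injected activity.
* **M2 (single point, intra-patient).**  The patient's own fitted
  reference curve is scaled by measured-ODR / curve-value at the
  measurement time; the dose scales identically.  Exact when the cycle is
  a positive multiple of the reference cycle.
* **M3 (single point, inter-patient).**  Fitted curves of the other
  patients are evaluated on a fixed 0–600 h grid (0.1 h step,
  configurable), divided by each contributor's injected activity,
  averaged pointwise, and integrated by the trapezoid rule; the template
  is scaled to the measured ODR (the latest one when several exist).
  Validated by leave-one-out: a patient never contributes to its own
  template.  Exact, up to grid interpolation, on a kinetically
  homogeneous cohort.
* **Missing whole cycles** are extrapolated as
  Σ(available) + mean(available) × n_missing.

All three estimators are 1-homogeneous in the measured ODR, and every
reported dose carries a method tag (TRIEXP_REF, M1, M2, M3, MONOEXP,
EXTRAPOLATED) plus donor/template provenance.

The workflow routes each (patient, cycle, VOI) by the priority
TRIEXP_REF > M1 > M2 > M3 and logs every decision.

## Quantitative-SPECT plumbing

Counts volumes convert to activity with an experimentally determined
camera sensitivity (e.g. 7.6 or 18 cps/MBq in tomographic mode): voxel
activity = (counts/duration)/sensitivity, concentration per voxel volume.
Count rates are corrected for detector dead time with the paralyzable
model m = n·e^{−τn}, inverted on its principal branch via the Lambert W
function (τ = 1.87 µs is the value used in the examples; rates beyond the
paralyzable peak raise a saturation error).  Dose-rate maps normalized to
1 MBq are scaled voxelwise to the total imaged activity.  The ODR of a
VOI is the arithmetic mean of dose-rate voxels inside its mask; when map
and mask grids differ, the *map* is resampled trilinearly onto the mask
grid (SimpleITK) — masks are never interpolated.  Units are tracked on
every volume and mismatches raise.

Monte Carlo particle transport is out of scope.  A **local-deposition**
operator (every decay deposits the mean β energy, ~147 keV, in its own
voxel; water density default) provides a desk-scale dose-rate map that is
explicitly tagged non-Monte-Carlo: it models self-dose only, no
cross-dose.  Synthetic fixtures generate dose-rate maps directly whenever
cross-dose matters.

## The virtual cohort generator

`CohortSpec` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 13 | cohort size |
| VOIs | LK, RK, L, S, L2L4 | kidneys, liver, spleen, marrow surrogate |
| k₁ | lognormal, median 3.5e-4 /s, σ 0.35 | uptake half-time ≈ 33 min |
| k₃ | lognormal, median 2.7e-6 /s, σ 0.26 | clearance half-time ≈ 71 h (biological) |
| k₂ / Ω₂ | 10·k₃ / 2·Ω₃ | population washout structure |
| Ω₃ scale | 9.4e-3 (kidneys) … 9.4e-4 (marrow) mGy/s, σ 0.4 | sets organ dose bands |
| injected activity | normal(6832, 158) MBq | per cycle |
| schedule | cycle 1: 1 h, 24 h, 96/144 h (alternating); cycles 2–4: 24 h | acquisition times ±15% jitter |
| inter-cycle amplitude CV | 0.10 | common factor, preserves zero-at-origin |
| inter-cycle k₃ CV | 0 (0.30 in divergence studies) | late-phase kinetic divergence |
| measurement noise CV | 0.05 | multiplicative log-normal |

Amplitude scales are chosen so per-cycle doses land in the clinically
reported magnitude bands (kidneys ≈ 3 Gy/cycle, liver/spleen ≈ 4–5 Gy,
vertebral marrow surrogates ≈ 0.3 Gy) — magnitudes only, not fits to any
patient.  Noise is multiplicative log-normal because dose rates are
positive.  Missingness rules remove listed (patient, cycle, slot)
acquisitions, emulating real availability tables.

The generator shares the fit's population washout structure
(k₂ = 10·k₃, Ω₂ = 2·Ω₃ per organ).  This is deliberate and should be kept
in mind when interpreting recovery results: simulate-then-fit tests
verify the implementation (decay handling, unit conversions, solver,
integration) under kinetics the three-point schedule can identify; they
do not show that three points could recover an arbitrary five-parameter
curve — no algorithm could.  Other features of real data the generator
does not emulate: reconstruction artifacts, spatially correlated noise,
segmentation variability, and cross-dose changes between cycles.

## Evaluation statistics

Percentage dose difference PDD = 100·(D_method − D_ref)/D_ref, signed.
Inter-cycle ODR variability: each cycle's ODR is rescaled by
(first activity / its activity) and the coefficient of variation
(sample sd, n−1, over mean, %) is reported.  Distributions are summarized
as [minimum; median; maximum; mean] with sd (undefined for n = 1).
Leave-one-out evaluation rebuilds M3 templates per held-out patient,
independently per cohort id, and skips (with a logged reason) patients
lacking a three-point reference fit.

## Numerical choices

* First-point tolerance 1e-5 mGy/s (≈ 1/1000 of a typical ODR); k₁
  bracket (k₂, 1e-2 /s]; k₃ ∈ [1e-9, k₁ᵐᵃˣ/ratio).
* Template grid 0–600 h at 0.1 h; trapezoid integration error is ~4e-5
  relative for typical kinetics, well below the 0.1% homogeneity
  tolerance used in tests.
* Closed-form integrals are cross-checked against adaptive quadrature
  over [0, 2000 h] plus the analytic tail beyond — the finite interval
  alone can miss up to ~2e-4 of the dose for the slowest clearances.
* CSV round-trips are exact: floats are written with shortest-exact
  `repr` and read with pandas' round-trip parser.

## Problem sizes

The test suite and the acceptance script use 1000 parameter draws for the
quadrature cross-check, 200 organs for fit recovery, 10–20 patients for
the template and cohort statistics, and 12 patients for the slot-ordering
study; a single three-point fit takes ≈50 ms, so the full suite runs in
well under a minute of compute.

## Known limitations

* The structural washout constants are population assumptions; organs
  whose washout deviates strongly from k₂ = 10·k₃ will be fitted with a
  compensating k₁ and slightly biased early-phase dose.
* The 600 h boundary condition conflicts with very slow clearances
  (biological half-life ≳ 140 h); such fits are flagged, not forced.
* The local-deposition operator ignores photon transport entirely; organ
  cross-dose must come from measured or synthetically generated dose-rate
  maps.
* The mono-exponential comparison fit is intentionally fragile (raises on
  rising pairs) — that fragility is the point of the comparison.
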