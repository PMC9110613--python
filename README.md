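# tridose

Adaptive organ dosimetry for ¹⁷⁷Lu-DOTATATE therapy from sparse
quantitative SPECT/CT schedules.

Peptide receptor radionuclide therapy delivers ~7.4 GBq of
¹⁷⁷Lu-DOTATATE per cycle, four cycles per treatment.  Estimating the
absorbed dose of kidneys, liver, spleen and bone-marrow surrogates
requires the organ's dose rate as a function of time — but clinical
practice rarely provides more than three SPECT/CT acquisitions in the
first cycle (≈1 h, 24 h, 96/144 h) and a single 24 h acquisition in the
following ones, with individual acquisitions often missing altogether.
`tridose` implements the full adaptive workflow for this situation, for
medical physicists and dosimetry researchers.

## The model

The organ-mean dose rate (ODR, mGy/s) is modelled as a tri-exponential
time dose-rate curve with uptake, rapid-washout and long-term-clearance
phases:

    TDRC(t) = −Ω₁e^{−(λ+k₁)t} + Ω₂e^{−(λ+k₂)t} + Ω₃e^{−(λ+k₃)t},
    Ω₁ = Ω₂ + Ω₃  (zero at injection),  k₁ > k₂ > k₃ ≥ 0

and the absorbed dose is its closed-form time integral

    D [Gy] = −Ω₁/(λ+k₁) + Ω₂/(λ+k₂) + Ω₃/(λ+k₃)   (converted from mGy).

Fits run on decay-corrected data with a zero boundary condition at 600 h;
the uptake rate k₁ is refined one-dimensionally until the model passes
through the earliest measurement within 1e-5 mGy/s.  When the schedule is
incomplete the workflow falls back, in priority order, to:

* **M1** — borrow the missing slot's ODR from another cycle of the same
  patient, scaled by injected activity, and refit;
* **M2** — scale the patient's own reference-cycle curve to a single
  measured point (similar-pharmacokinetics assumption);
* **M3** — scale a leave-one-out population-average curve to the single
  point.

The package also ships the quantitative-SPECT plumbing (sensitivity
calibration, paralyzable dead-time inversion, dose-rate-map scaling, VOI
mean extraction with trilinear map resampling, NIfTI/MetaImage I/O), the
evaluation statistics (signed percentage dose difference, activity-scaled
inter-cycle variation coefficients, [min; median; max; mean] summaries,
leave-one-out protocols) and a virtual-cohort generator with exact
tri-exponential ground truth, so every estimator is testable without
clinical data.  See `docs/methods.md` for the full model account.

## Worked example

`examples/01_fit_and_integrate.py` samples a kidney-like organ at the
clinical schedule and refits it:

```
measured ODR at    1.0 h : 1.5565e-02 mGy/s
measured ODR at   24.0 h : 7.1064e-03 mGy/s
measured ODR at   96.0 h : 2.0740e-03 mGy/s

converged: True  (first-point gap 4.7e-06 mGy/s)
fitted dose     : 2.5462 Gy
ground truth    : 2.5463 Gy
```

The three measured dose rates trace the washout of the curve; the fit
reconstructs the full curve (zero at injection, through all three
points) and its closed-form integral — here 2.55 Gy for the cycle —
matches the generating kinetics to 0.004%.

`examples/02_sparse_schedules.py` shows the three fallbacks on a
conserved-kinetics patient (all exact in that limit),
`examples/03_virtual_cohort_workflow.py` routes a 13-patient virtual
cohort through the adaptive workflow (kidneys ≈ 3 Gy/cycle, marrow
surrogate ≈ 0.22 Gy/cycle, median inter-cycle 24 h ODR variation 10.6%),
and `examples/04_quantitative_imaging.py` walks a voxel phantom from
counts to organ dose rates.

A thin CLI wraps the same library functions:

```bash
tridose simulate --seed 5 --out-csv cohort.csv --truth-json truth.json
tridose fit cohort.csv --doses-csv doses.csv --fits-json fits.json
tridose evaluate cohort.csv --out-csv report.csv
tridose template cohort.csv --voi LK --out-csv template.csv
```

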