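"""M1/M2/M3 fallback estimators and missing-cycle extrapolation."""

import numpy as np
import pytest

from tridose.fitting import FitResult, Slot, TimePointMeasurement
from tridose.kinetics import (
    MethodTag,
    TriExpParams,
    evaluate_tdrc,
    integrate_tdrc,
)
from tridose.sparse import (
    CycleRecord,
    FallbackUnavailableError,
    InsufficientCohortError,
    PopulationTemplate,
    UnusableTimeError,
    build_population_template,
    extrapolate_missing_cycles,
    m1_substitute_odr,
    m2_stp_intra,
    m3_stp_inter,
)
from tridose.synthetic import make_conserved_kinetics_patient

from .conftest import draw_valid_params


def exact_fit(params: TriExpParams) -> FitResult:
    """A FitResult wrapping known-true parameters (zero residuals)."""
    return FitResult(
        params=params, residuals=np.zeros(3), first_point_gap=0.0,
        converged=True,
    )


@pytest.fixture()
def base_params(kidney_params):
    return {"LK": kidney_params}


class TestM1:
    def test_substituted_odr_scales_with_activity(self, base_params):
        patient, _ = make_conserved_kinetics_patient(
            base_params, cycle_scales=[1.0, 0.5],
            activities_mbq=[7400.0, 3700.0],
        )
        donor = patient.cycle(1)
        target = CycleRecord(cycle_id=2, injected_activity_mbq=3700.0)
        target.measurements["LK"] = [
            p for p in patient.cycle(2).points("LK") if p.nominal_slot != Slot.H24
        ]
        sub, fit = m1_substitute_odr(target, [donor], "LK", Slot.H24, seed=0)
        donor_24 = donor.slot_point("LK", Slot.H24)
        assert sub.odr == pytest.approx(donor_24.odr * 0.5, rel=1e-12)
        assert sub.t_hours == donor_24.t_hours  # donor's exact time is used
        assert fit.converged

    def test_exact_when_kinetics_conserved_with_activity(self, base_params, lam):
        # cycles differ only by an amplitude scale proportional to activity:
        # the substituted point equals the true missing one, so the M1 fit is
        # the reference fit on identical data
        patient, truth = make_conserved_kinetics_patient(
            base_params, cycle_scales=[1.0, 0.75],
        )
        target_full = patient.cycle(2)
        target = CycleRecord(cycle_id=2,
                             injected_activity_mbq=target_full.injected_activity_mbq)
        target.measurements["LK"] = [
            p for p in target_full.points("LK") if p.nominal_slot != Slot.H24
        ]
        sub, m1_fit = m1_substitute_odr(
            target, [patient.cycle(1)], "LK", Slot.H24, lam=lam, seed=0
        )
        true_point = target_full.slot_point("LK", Slot.H24)
        assert sub.odr == pytest.approx(true_point.odr, rel=1e-12)
        from tridose.fitting import fit_triexp

        ref_fit = fit_triexp(target_full.points("LK"), lam=lam, seed=0)
        assert integrate_tdrc(m1_fit.params) == pytest.approx(
            integrate_tdrc(ref_fit.params), rel=1e-9
        )

    def test_nearest_donor_with_earlier_tie_break(self, base_params):
        patient, _ = make_conserved_kinetics_patient(
            base_params, cycle_scales=[1.0, 1.0, 1.0, 1.0]
        )
        target_full = patient.cycle(2)
        target = CycleRecord(cycle_id=2,
                             injected_activity_mbq=target_full.injected_activity_mbq)
        target.measurements["LK"] = [
            p for p in target_full.points("LK") if p.nominal_slot != Slot.H24
        ]
        donors = [patient.cycle(i) for i in (1, 3, 4)]
        # record the chosen donor through provenance: cycles 1 and 3 tie at
        # distance 1; the earlier cycle must win
        sub, _ = m1_substitute_odr(target, donors, "LK", Slot.H24, seed=0)
        assert sub.odr == pytest.approx(
            patient.cycle(1).slot_point("LK", Slot.H24).odr, rel=1e-12
        )

    def test_no_donor_raises(self, base_params):
        patient, _ = make_conserved_kinetics_patient(base_params, [1.0])
        target = patient.cycle(1)
        with pytest.raises(FallbackUnavailableError):
            m1_substitute_odr(target, [], "LK", Slot.H24)


class TestM2:
    def test_scale_one_returns_reference_dose(self, kidney_params):
        fit = exact_fit(kidney_params)
        dose1 = integrate_tdrc(kidney_params)
        odr = float(evaluate_tdrc(kidney_params, 24.0 * 3600.0))
        single = TimePointMeasurement(t_hours=24.0, odr=odr, cycle_id=2)
        est = m2_stp_intra(fit, dose1, single)
        assert est.value == pytest.approx(dose1, rel=1e-12)
        assert est.method_tag is MethodTag.M2

    def test_half_scale_halves_dose(self, kidney_params):
        fit = exact_fit(kidney_params)
        curve_24 = float(evaluate_tdrc(kidney_params, 24.0 * 3600.0))
        single = TimePointMeasurement(t_hours=24.0, odr=0.5 * curve_24, cycle_id=2)
        est = m2_stp_intra(fit, 3.0, single)
        assert est.value == pytest.approx(1.5, rel=1e-12)

    @pytest.mark.parametrize("scale", [0.37, 1.0, 2.8])
    @pytest.mark.parametrize("t_hours", [1.0, 24.0, 96.0])
    def test_exact_under_conserved_kinetics(self, kidney_params, scale, t_hours):
        fit = exact_fit(kidney_params)
        dose1 = integrate_tdrc(kidney_params)
        odr = scale * float(evaluate_tdrc(kidney_params, t_hours * 3600.0))
        single = TimePointMeasurement(t_hours=t_hours, odr=odr, cycle_id=4)
        est = m2_stp_intra(fit, dose1, single)
        assert abs(est.value / (scale * dose1) - 1.0) < 1e-12

    def test_time_beyond_curve_support_rejected(self, kidney_params):
        fit = exact_fit(kidney_params)
        # at very late times the negative uptake term is gone but the value
        # underflows to zero
        single = TimePointMeasurement(t_hours=50000.0, odr=1e-5)
        with pytest.raises(UnusableTimeError):
            m2_stp_intra(fit, 3.0, single)


class TestPopulationTemplate:
    def test_identical_normalized_curves_average_to_member(self, kidney_params):
        fits = {f"P{i}": exact_fit(kidney_params) for i in range(3)}
        acts = {f"P{i}": 7400.0 for i in range(3)}
        tmpl = build_population_template(fits, acts, "LK")
        member = evaluate_tdrc(kidney_params,
                               tmpl.time_grid_hours * 3600.0) / 7400.0
        np.testing.assert_allclose(tmpl.mean_curve, np.clip(member, 0, None),
                                   rtol=1e-12)

    def test_pointwise_mean_of_two_contributors(self, kidney_params, lam):
        double = TriExpParams(
            kidney_params.omega1 * 2, kidney_params.omega2 * 2,
            kidney_params.omega3 * 2, kidney_params.k1, kidney_params.k2,
            kidney_params.k3, lam,
        )
        fits = {"A": exact_fit(kidney_params), "B": exact_fit(double)}
        acts = {"A": 7400.0, "B": 7400.0}
        tmpl = build_population_template(fits, acts, "LK")
        small = np.clip(
            evaluate_tdrc(kidney_params, tmpl.time_grid_hours * 3600.0) / 7400.0,
            0, None,
        )
        np.testing.assert_allclose(tmpl.mean_curve, 1.5 * small, rtol=1e-10)

    def test_leave_one_out_bookkeeping(self, kidney_params):
        fits = {f"P{i}": exact_fit(kidney_params) for i in range(3)}
        acts = {f"P{i}": 7400.0 for i in range(3)}
        for pid in fits:
            tmpl = build_population_template(fits, acts, "LK", leave_out=pid)
            assert tmpl.n_contributors == 2
            assert pid not in tmpl.contributor_ids

    def test_empty_contributors_raise(self, kidney_params):
        with pytest.raises(InsufficientCohortError):
            build_population_template(
                {"A": exact_fit(kidney_params)}, {"A": 7400.0}, "LK",
                leave_out="A",
            )


class TestM3:
    def test_homogeneous_cohort_recovers_dose(self, kidney_params):
        fits = {f"P{i}": exact_fit(kidney_params) for i in range(4)}
        acts = {f"P{i}": 7400.0 for i in range(4)}
        tmpl = build_population_template(fits, acts, "LK", leave_out="P0")
        true_dose = integrate_tdrc(kidney_params)
        for t in (1.0, 24.0, 96.0):
            odr = float(evaluate_tdrc(kidney_params, t * 3600.0))
            est = m3_stp_inter(
                tmpl, TimePointMeasurement(t_hours=t, odr=odr, cycle_id=2)
            )
            assert abs(est.value / true_dose - 1.0) < 1e-3
            assert est.method_tag is MethodTag.M3

    def test_measured_equal_to_template_gives_integral(self, kidney_params):
        fits = {"A": exact_fit(kidney_params), "B": exact_fit(kidney_params)}
        acts = {"A": 7400.0, "B": 7400.0}
        tmpl = build_population_template(fits, acts, "LK")
        odr = tmpl.value_at(24.0)
        est = m3_stp_inter(tmpl, TimePointMeasurement(t_hours=24.0, odr=odr))
        assert est.value == pytest.approx(tmpl.integral_gy_per_mbq, rel=1e-12)

    def test_latest_of_several_measurements_wins(self, kidney_params):
        fits = {"A": exact_fit(kidney_params), "B": exact_fit(kidney_params)}
        acts = {"A": 7400.0, "B": 7400.0}
        tmpl = build_population_template(fits, acts, "LK")
        pts = [
            TimePointMeasurement(t_hours=24.0, odr=tmpl.value_at(24.0) * 5.0),
            TimePointMeasurement(t_hours=96.0, odr=tmpl.value_at(96.0)),
        ]
        est = m3_stp_inter(tmpl, pts)  # latest point has unit scale
        assert est.value == pytest.approx(tmpl.integral_gy_per_mbq, rel=1e-12)

    def test_off_cluster_patient_errs_more(self, lam):
        # two-cluster cohort: the template built from cluster A misestimates
        # a cluster-B patient more than an on-cluster patient
        rng = np.random.default_rng(2)
        a = draw_valid_params(rng)
        b = TriExpParams(a.omega1, a.omega2, a.omega3,
                         a.k1, a.k2 * 2.0, a.k3 * 2.0, lam)
        fits = {f"A{i}": exact_fit(a) for i in range(3)}
        acts = {f"A{i}": 7400.0 for i in range(3)}
        acts.update({"B": 7400.0})
        tmpl = build_population_template(fits, acts, "LK")
        t = 24.0
        for params, expect_small in ((a, True), (b, False)):
            odr = float(evaluate_tdrc(params, t * 3600.0))
            est = m3_stp_inter(tmpl, TimePointMeasurement(t_hours=t, odr=odr))
            err = abs(est.value / integrate_tdrc(params) - 1.0)
            if expect_small:
                err_on = err
            else:
                err_off = err
        assert err_off > err_on

    def test_time_outside_grid_rejected(self, kidney_params):
        fits = {"A": exact_fit(kidney_params), "B": exact_fit(kidney_params)}
        acts = {"A": 7400.0, "B": 7400.0}
        tmpl = build_population_template(fits, acts, "LK")
        with pytest.raises(UnusableTimeError):
            m3_stp_inter(tmpl, TimePointMeasurement(t_hours=601.0, odr=1e-4))


class TestHomogeneityDegree:
    def test_estimators_scale_linearly_in_measured_odr(self, kidney_params):
        fit = exact_fit(kidney_params)
        dose1 = integrate_tdrc(kidney_params)
        fits = {"A": fit, "B": fit}
        acts = {"A": 7400.0, "B": 7400.0}
        tmpl = build_population_template(fits, acts, "LK")
        t, odr = 24.0, 4e-3
        one = TimePointMeasurement(t_hours=t, odr=odr)
        two = TimePointMeasurement(t_hours=t, odr=2 * odr)
        assert m2_stp_intra(fit, dose1, two).value == pytest.approx(
            2 * m2_stp_intra(fit, dose1, one).value, rel=1e-12
        )
        assert m3_stp_inter(tmpl, two).value == pytest.approx(
            2 * m3_stp_inter(tmpl, one).value, rel=1e-12
        )


class TestExtrapolation:
    def test_mean_times_missing_cycles(self):
        est = extrapolate_missing_cycles([3.0, 3.0, 2.4], 1)
        assert est.value == pytest.approx(11.2, rel=1e-12)
        assert est.method_tag is MethodTag.EXTRAPOLATED

    def test_zero_missing_is_plain_sum(self):
        assert extrapolate_missing_cycles([1.0, 2.0], 0).value == pytest.approx(3.0)

    def test_single_cycle_extrapolates_proportionally(self):
        assert extrapolate_missing_cycles([2.5], 3).value == pytest.approx(10.0)

    def test_empty_rejected(self):
        from tridose.fitting import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            extrapolate_missing_cycles([], 1)

    def test_dose_tags_survive_serialization(self):
        rec = extrapolate_missing_cycles([1.0], 0).to_record()
        assert rec["method_tag"] == "EXTRAPOLATED"
        assert rec["value_Gy"] == 1.0
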