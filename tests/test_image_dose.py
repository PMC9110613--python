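"""Quantitative-SPECT plumbing: calibration, dead time, VOI statistics, I/O."""

import math

import numpy as np
import pytest

from tridose.image_dose import (
    CalibrationConfig,
    EmptyVoiError,
    GeometryError,
    SaturationError,
    ScalarVolume,
    UnitError,
    VoiMask,
    compute_odr,
    counts_to_activity,
    deadtime_correct,
    deadtime_forward,
    local_deposition_map,
    read_volume,
    scale_dose_rate_map,
    write_volume,
)


def fixed_point_deadtime_oracle(m: float, tau: float, n_iter: int = 200) -> float:
    """Independent oracle: iterate n = m * exp(+tau * n) to convergence."""
    n = m
    for _ in range(n_iter):
        n = m * math.exp(tau * n)
    return n


@pytest.fixture()
def counts_volume():
    vals = np.zeros((4, 4, 4))
    vals[1, 2, 3] = 6840.0
    return ScalarVolume(values=vals, spacing=(4.4, 4.4, 4.4), unit="counts")


class TestCalibration:
    def test_single_voxel_sensitivity_example(self, counts_volume):
        # 6840 counts over 900 s at 7.6 cps/MBq is exactly 1 MBq
        cal = CalibrationConfig(sensitivity_cps_per_mbq=7.6,
                                acquisition_duration_s=900.0)
        conc, total = counts_to_activity(counts_volume, cal)
        assert total == pytest.approx(1.0, rel=1e-12)
        assert conc.unit == "MBq/mL"
        voxel_ml = 4.4**3 / 1000.0
        assert conc.values[1, 2, 3] == pytest.approx(1.0 / voxel_ml, rel=1e-12)

    def test_zero_counts_zero_activity(self):
        vol = ScalarVolume(np.zeros((3, 3, 3)), spacing=(4.4, 4.4, 4.4))
        _, total = counts_to_activity(vol, CalibrationConfig(18.0))
        assert total == 0.0

    def test_linearity_in_sensitivity(self, counts_volume):
        a = counts_to_activity(
            counts_volume, CalibrationConfig(7.6, acquisition_duration_s=900.0)
        )
        b = counts_to_activity(
            counts_volume, CalibrationConfig(15.2, acquisition_duration_s=900.0)
        )
        assert b[1] == pytest.approx(a[1] / 2.0, rel=1e-12)
        np.testing.assert_allclose(b[0].values, a[0].values / 2.0)

    def test_unit_mismatch_raises(self, counts_volume):
        wrong = ScalarVolume(counts_volume.values, counts_volume.spacing,
                             unit="mGy/s")
        with pytest.raises(UnitError):
            counts_to_activity(wrong, CalibrationConfig(7.6))


class TestDeadTime:
    def test_zero_tau_identity(self):
        assert deadtime_correct(12345.0, 0.0) == 12345.0

    def test_paralyzable_inverse_matches_fixed_point_oracle(self):
        tau = 1.87e-6
        m = 1.0e4
        expected = fixed_point_deadtime_oracle(m, tau)
        n = deadtime_correct(m, tau)
        assert n == pytest.approx(expected, rel=1e-9)
        assert n == pytest.approx(1.0192e4, rel=1e-4)
        assert n >= m

    def test_round_trip_identity_on_solvable_branch(self):
        tau = 1.87e-6
        for n_true in np.geomspace(10.0, 2e5, 25):
            m = deadtime_forward(n_true, tau)
            assert deadtime_correct(m, tau) == pytest.approx(n_true, rel=1e-9)

    def test_correction_factor_monotone_in_rate(self):
        tau = 1.87e-6
        rates = np.linspace(1e3, 1.5e5, 40)
        factors = [deadtime_correct(m, tau) / m for m in rates]
        assert np.all(np.diff(factors) > 0)

    def test_saturation_raises(self):
        tau = 1.87e-6
        with pytest.raises(SaturationError):
            deadtime_correct(1.01 / (math.e * tau), tau)


class TestDoseRateMaps:
    def test_scaling_examples(self):
        unit_map = ScalarVolume(
            np.full((2, 2, 2), 3e-7), spacing=(4.4, 4.4, 4.4),
            unit="mGy/s per MBq",
        )
        zero = scale_dose_rate_map(unit_map, 0.0)
        assert not zero.values.any() and zero.unit == "mGy/s"
        one = scale_dose_rate_map(unit_map, 5000.0)
        two = scale_dose_rate_map(unit_map, 10000.0)
        np.testing.assert_allclose(two.values, 2.0 * one.values)
        np.testing.assert_allclose(one.values, 3e-7 * 5000.0)
        with pytest.raises(ValueError):
            scale_dose_rate_map(unit_map, -1.0)

    def test_local_deposition_single_hot_voxel(self):
        spacing = (4.0, 4.0, 4.0)
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 2.5  # MBq/mL
        act = ScalarVolume(vals, spacing, unit="MBq/mL")
        energy = 2.0e-14  # J per decay
        out = local_deposition_map(act, mean_energy_per_decay_j=energy)
        assert out.unit == "mGy/s per MBq"
        voxel_ml = 4.0**3 / 1000.0
        total_mbq = 2.5 * voxel_ml
        # closed form: C * 1e6 * E / (1 g/mL * 1e-3 kg/mL) -> Gy/s, x1e3 -> mGy/s
        expected = 2.5 * 1e6 * energy / 1e-3 * 1e3 / total_mbq
        assert out.values[1, 1, 1] == pytest.approx(expected, rel=1e-12)
        assert out.values[0, 0, 0] == 0.0

    def test_local_deposition_linearity(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.0, 1.0, (4, 4, 4))
        a = local_deposition_map(ScalarVolume(vals, (4.0,) * 3, unit="MBq/mL"))
        b = local_deposition_map(ScalarVolume(2 * vals, (4.0,) * 3, unit="MBq/mL"))
        # per-MBq normalization cancels a global activity factor
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestComputeOdr:
    def test_three_voxel_mean(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0], vals[0, 0, 1], vals[0, 1, 0] = 1.0, 2.0, 3.0
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = mask[0, 1, 0] = True
        vol = ScalarVolume(vals, (4.4,) * 3, unit="mGy/s")
        voi = VoiMask(mask, "LK", (4.4,) * 3)
        assert compute_odr(vol, voi) == pytest.approx(2.0)

    def test_uniform_map_any_mask(self):
        vol = ScalarVolume(np.full((5, 5, 5), 0.7), (2.0,) * 3, unit="mGy/s")
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(5, 5, 5)) > 0.6
        mask[0, 0, 0] = True
        voi = VoiMask(mask, "S", (2.0,) * 3)
        assert compute_odr(vol, voi) == pytest.approx(0.7, rel=1e-12)

    def test_matches_naive_voxel_loop(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0.0, 1e-2, (6, 7, 8))
        mask = rng.uniform(size=(6, 7, 8)) > 0.5
        mask[0, 0, 0] = True
        vol = ScalarVolume(vals, (4.4,) * 3, unit="mGy/s")
        voi = VoiMask(mask, "L", (4.4,) * 3)
        total, n = 0.0, 0
        for i in range(6):
            for j in range(7):
                for k in range(8):
                    if mask[i, j, k]:
                        total += vals[i, j, k]
                        n += 1
        assert compute_odr(vol, voi) == pytest.approx(total / n, rel=1e-12)

    def test_padding_outside_mask_is_irrelevant(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        voi = VoiMask(mask, "RK", (4.4,) * 3)
        a = compute_odr(ScalarVolume(vals, (4.4,) * 3, unit="mGy/s"), voi)
        padded = vals.copy()
        padded[~mask] = 99.0
        b = compute_odr(ScalarVolume(padded, (4.4,) * 3, unit="mGy/s"), voi)
        assert a == b

    def test_resampling_onto_finer_mask_grid(self):
        # uniform dose map on a coarse grid; mask on a 2x finer grid
        vol = ScalarVolume(np.full((4, 4, 4), 5.0), (8.8,) * 3, unit="mGy/s")
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        voi = VoiMask(mask, "LK", (4.4,) * 3)
        assert compute_odr(vol, voi) == pytest.approx(5.0, rel=1e-6)
        with pytest.raises(GeometryError):
            compute_odr(vol, voi, resample=False)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyVoiError):
            VoiMask(np.zeros((2, 2, 2), dtype=bool), "BG", (4.4,) * 3)


class TestVolumeIo:
    @pytest.mark.parametrize("suffix", [".nii.gz", ".mha"])
    def test_geometry_round_trip(self, tmp_path, suffix):
        rng = np.random.default_rng(9)
        vol = ScalarVolume(
            rng.uniform(size=(3, 4, 5)),
            spacing=(4.4, 2.2, 1.1),
            origin=(-10.0, 5.0, 2.5),
            unit="mGy/s",
        )
        path = tmp_path / f"vol{suffix}"
        write_volume(path, vol)
        back = read_volume(path, unit="mGy/s")
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-12)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_mask_round_trip(self, tmp_path):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        voi = VoiMask(mask, "LK", (4.4,) * 3)
        path = tmp_path / "mask.nii.gz"
        write_volume(path, voi)
        back = read_volume(path, as_mask=True, label="LK")
        np.testing.assert_array_equal(back.values, mask)
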