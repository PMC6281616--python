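"""Morphometry pipeline tests: calibration slopes, radius conversion,
coupling statistics, kinetics, FRAP, growth rates."""

import numpy as np
import pytest

from memtube.morphometry import (
    BulgeRecord,
    CalibrationError,
    FissionEvent,
    FrapTrace,
    GrowthRate,
    calibrate_k1,
    calibrate_k2,
    detect_bulges,
    fission_kinetics,
    fit_frap,
    pearson_protein_membrane,
    protein_membrane_ratio,
    radius_from_integrated_density,
    radius_profile,
    remodeling_probability,
    scaffold_growth_rate,
)

PX = 80.0  # nm per pixel used throughout


class TestCalibrateK1:
    def _slb(self, density, shape=(64, 64), noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        img = np.full(shape, density * PX**2)
        if noise:
            img = img + rng.normal(0, noise * img.mean(), shape)
        return img

    def test_recovers_uniform_density(self):
        img = self._slb(3.0, noise=0.02)
        rois = [(2, 2, 8, 8), (12, 12, 16, 16), (30, 5, 24, 24), (5, 40, 12, 10)]
        cal = calibrate_k1(img, rois, PX)
        assert cal.k1 == pytest.approx(3.0, rel=0.02)

    def test_identical_roi_areas_rejected(self):
        img = self._slb(3.0)
        rois = [(0, 0, 8, 8), (10, 10, 8, 8), (20, 20, 8, 8)]
        with pytest.raises(CalibrationError):
            calibrate_k1(img, rois, PX)

    def test_doubling_intensities_doubles_k1(self):
        img = self._slb(3.0)
        rois = [(2, 2, 8, 8), (12, 12, 16, 16), (30, 5, 24, 24)]
        k1 = calibrate_k1(img, rois, PX).k1
        k1b = calibrate_k1(2.0 * img, rois, PX).k1
        assert k1b == pytest.approx(2.0 * k1, rel=1e-12)

    def test_negative_slope_rejected(self):
        img = -self._slb(3.0)
        rois = [(2, 2, 8, 8), (12, 12, 16, 16), (30, 5, 24, 24)]
        with pytest.raises(CalibrationError):
            calibrate_k1(img, rois, PX)

    def test_too_few_rois_rejected(self):
        img = self._slb(3.0)
        with pytest.raises(CalibrationError):
            calibrate_k1(img, [(0, 0, 8, 8), (0, 0, 4, 4)], PX)


class TestRadiusFromID:
    def test_zero_signal_gives_zero_radius(self):
        assert radius_from_integrated_density(0.0, 20.0, 250.0) == 0.0

    def test_unit_case(self):
        assert radius_from_integrated_density(2.0 * np.pi, 1.0, 1.0) == pytest.approx(1.0)

    def test_forward_inverse_roundtrip(self):
        # ID assembled as r * k1 * 2 pi l must invert to r
        ID = 10.0 * 250.0 * 2.0 * np.pi * 20.0
        assert radius_from_integrated_density(ID, 20.0, 250.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("l,k1", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, l, k1):
        with pytest.raises(ValueError):
            radius_from_integrated_density(1.0, l, k1)


class TestCalibrateK2:
    def _tubes(self, radii, k=30.0, noise=0.01, seed=1):
        rng = np.random.default_rng(seed)
        out = []
        for r in radii:
            img = np.zeros((21, 40))
            img[10] = k * r
            img = img + rng.normal(0, noise * k * max(radii), img.shape)
            out.append(img)
        return out

    def test_recovers_render_constant(self):
        radii = [5.0, 10.0, 20.0, 40.0]
        cal = calibrate_k2(self._tubes(radii), radii)
        assert cal.k2 == pytest.approx(30.0, rel=0.05)

    def test_single_tube_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_k2(self._tubes([10.0]), [10.0])

    def test_narrow_radius_range_warns(self):
        radii = [10.0, 11.0, 12.0]
        with pytest.warns(UserWarning):
            calibrate_k2(self._tubes(radii), radii)

    def test_scaling_radii_halves_slope(self):
        radii = np.array([5.0, 10.0, 20.0, 40.0])
        tubes = self._tubes(radii, noise=0.0)
        k2 = calibrate_k2(tubes, radii).k2
        k2b = calibrate_k2(tubes, 2.0 * radii).k2
        assert k2b == pytest.approx(0.5 * k2, rel=1e-9)


class TestRadiusProfile:
    def test_flat_trace(self):
        r = radius_profile(np.full(50, 30.0 * 10.0), k2=30.0)
        assert np.allclose(r, 10.0)

    def test_zero_trace(self):
        assert np.all(radius_profile(np.zeros(10), k2=5.0) == 0.0)

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            r = radius_profile(np.array([-3.0, 30.0]), k2=30.0)
        assert r[0] == 0.0

    def test_invalid_k2(self):
        with pytest.raises(ValueError):
            radius_profile(np.ones(5), k2=0.0)


class TestProteinMembraneCoupling:
    def test_identical_channels_ratio_one(self):
        img = np.random.default_rng(0).uniform(1, 2, (20, 20))
        assert protein_membrane_ratio(img, img, (0, 0, 20, 20)) == pytest.approx(1.0)

    def test_eightfold_tube_enrichment_scenario(self):
        """Tube ROI with 8x protein density vs SLB ROI at 1x: the
        ratio-of-ratios reports the eightfold curvature enrichment."""
        membrane = np.ones((10, 40))
        protein = np.ones((10, 40))
        protein[:, :20] *= 8.0  # tube region
        tube = protein_membrane_ratio(protein, membrane, (0, 0, 10, 20))
        slb = protein_membrane_ratio(protein, membrane, (0, 20, 10, 20))
        assert tube / slb == pytest.approx(8.0)

    def test_zero_protein_channel(self):
        assert protein_membrane_ratio(np.zeros((5, 5)), np.ones((5, 5)), (0, 0, 5, 5)) == 0.0

    def test_zero_membrane_undefined(self):
        with pytest.raises(ValueError):
            protein_membrane_ratio(np.ones((5, 5)), np.zeros((5, 5)), (0, 0, 5, 5))

    def test_pearson_perfect_linear(self):
        p = np.linspace(1, 5, 30)
        assert pearson_protein_membrane(p, 2.0 * p + 1.0) == pytest.approx(1.0)
        assert pearson_protein_membrane(p, -0.5 * p + 9.0) == pytest.approx(-1.0)

    def test_pearson_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_protein_membrane(np.ones(10), np.linspace(0, 1, 10))


class TestDetectBulges:
    def test_flat_profile_no_bulges(self):
        recs, density = detect_bulges(np.full(200, 10.0), PX)
        assert recs == [] and density == 0.0

    def test_three_bulges_on_10um_tube(self):
        n = int(10000 / PX)
        r = np.full(n, 10.0)
        for pos in (2000, 5000, 8000):
            k = int(pos / PX)
            r[k - 2 : k + 3] = 15.0
        recs, density = detect_bulges(r, PX)
        assert len(recs) == 3
        assert density == pytest.approx(0.3, rel=1e-9)
        for rec, pos in zip(recs, (2000, 5000, 8000)):
            assert abs(rec.position - pos) < 3 * PX
            assert rec.radius == pytest.approx(15.0)

    def test_nearby_bulges_merge(self):
        n = int(10000 / PX)
        r = np.full(n, 10.0)
        k = int(5000 / PX)
        r[k - 2 : k] = 15.0
        r[k + 1 : k + 3] = 15.0  # 1-px gap < 200 nm merge distance
        recs, _ = detect_bulges(r, PX)
        assert len(recs) == 1

    def test_short_tube_rejected(self):
        with pytest.raises(ValueError):
            detect_bulges(np.full(5, 10.0), PX, baseline_window=2000.0)

    def test_constriction_mode(self):
        n = int(10000 / PX)
        r = np.full(n, 20.0)
        k = int(5000 / PX)
        r[k - 2 : k + 3] = 11.0
        recs, _ = detect_bulges(r, PX, detect_constrictions=True)
        assert len(recs) == 1
        assert recs[0].constriction
        assert recs[0].radius == pytest.approx(11.0)


class TestFissionKinetics:
    def test_no_events_flat_curve(self):
        out = fission_kinetics([], (0, 100))
        assert np.all(out["cumulative"]([0, 50, 100]) == 0)

    def test_fission_time_is_difference(self):
        ev = FissionEvent(tube_id=1, onset_time=10.0, scission_time=70.0)
        out = fission_kinetics([ev], (0, 100))
        assert out["fission_times"][0] == pytest.approx(60.0)

    def test_rejects_scission_before_onset(self):
        good = FissionEvent(1, 5.0, 20.0)
        bad = FissionEvent(2, 30.0, 10.0)
        with pytest.warns(UserWarning):
            out = fission_kinetics([good, bad], (0, 100))
        assert len(out["events"]) == 1

    def test_cumulative_curve_nondecreasing_and_exponential_mean(self):
        """Events drawn with exponential fission times at rate lam: the
        fitted mean must sit within 2 SE of 1/lam (simulation oracle)."""
        rng = np.random.default_rng(42)
        lam = 0.1
        n = 200
        ft = rng.exponential(1.0 / lam, n)
        events = [FissionEvent(i, 10.0, 10.0 + f) for i, f in enumerate(ft)]
        out = fission_kinetics(events, (0, 1e9))
        mean = out["fission_times"].mean()
        se = out["fission_times"].std(ddof=1) / np.sqrt(n)
        assert abs(mean - 1.0 / lam) < 2 * se + 1e-9
        t = np.linspace(0, 500, 200)
        c = out["cumulative"](t)
        assert np.all(np.diff(c) >= 0)


class TestRemodelingProbability:
    def test_all_remodeled(self):
        tubes = [(5.0, True, False), (12.0, True, True), (18.0, True, True)]
        out = remodeling_probability(tubes, [0, 10, 20])
        assert np.allclose(out["p_remodeled"][~out["empty"]], 1.0)

    def test_threshold_step_below_25nm(self):
        rng = np.random.default_rng(3)
        tubes = []
        for r in rng.uniform(5, 45, 200):
            tubes.append((r, r < 25.0, r < 25.0 and rng.random() < 0.8))
        out = remodeling_probability(tubes, [0, 12.5, 25, 37.5, 50])
        assert out["p_remodeled"][0] == 1.0 and out["p_remodeled"][1] == 1.0
        assert out["p_remodeled"][2] == 0.0 and out["p_remodeled"][3] == 0.0

    def test_single_tube_bin_has_wide_ci(self):
        out = remodeling_probability([(5.0, True, True)], [0, 10])
        lo, hi = out["ci_remodeled"][0]
        assert lo < 0.25 and hi == pytest.approx(1.0, abs=1e-9)

    def test_empty_bin_flagged(self):
        out = remodeling_probability([(5.0, True, True)], [0, 10, 20])
        assert out["empty"][1]
        assert np.isnan(out["p_remodeled"][1])


class TestFitFrap:
    def test_full_recovery_mobile_fraction_one(self):
        t = np.arange(60) * 0.5
        y = 20.0 + (100.0 - 20.0) * t / (3.0 + t)
        fit = fit_frap(FrapTrace(100.0, t, y))
        assert fit.mobile_fraction == pytest.approx(1.0, abs=0.02)
        assert fit.half_time == pytest.approx(3.0, rel=0.05)

    def test_no_bleach_rejected(self):
        t = np.arange(20) * 1.0
        with pytest.raises(ValueError):
            fit_frap(FrapTrace(50.0, t, np.full(20, 50.0)))

    def test_too_few_points_rejected(self):
        t = np.arange(5) * 1.0
        with pytest.raises(ValueError):
            fit_frap(FrapTrace(50.0, t, np.linspace(10, 30, 5)))

    def test_exponential_model_agrees_on_plateau(self):
        t = np.arange(80) * 0.5
        f_inf = 60.0
        y = f_inf - (f_inf - 20.0) * np.exp(-np.log(2) * t / 4.0)
        fit = fit_frap(FrapTrace(100.0, t, y), model="exponential")
        assert fit.mobile_fraction == pytest.approx(0.5, abs=0.02)


class TestScaffoldGrowthRate:
    def _kymo(self, speed, n_lines=50, interval=0.2, n_px=50):
        kymo = np.zeros((n_lines, n_px))
        for row in range(n_lines):
            edge_px = int((200.0 + speed * row * interval) / PX)
            kymo[row, : edge_px + 1] = 100.0
        return kymo

    def test_recovers_advancing_edge(self):
        rate = scaffold_growth_rate(self._kymo(27.0), PX, frame_interval=0.2)
        assert rate.rate == pytest.approx(27.0, rel=0.05)

    def test_static_edge_zero_rate(self):
        rate = scaffold_growth_rate(self._kymo(0.0), PX, frame_interval=0.2)
        assert rate.rate == 0.0
        assert rate.low_confidence

    def test_reversed_time_flips_sign(self):
        kymo = self._kymo(27.0)
        fwd = scaffold_growth_rate(kymo, PX, frame_interval=0.2)
        rev = scaffold_growth_rate(kymo[::-1], PX, frame_interval=0.2)
        assert rev.rate == pytest.approx(-fwd.rate, rel=0.05)
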