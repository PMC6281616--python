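"""Generator tests: rendering linearity, area conservation, ground-truth
logs, and generator/detector round trips."""

import numpy as np
import pytest

from memtube.morphometry import (
    calibrate_k1,
    calibrate_k2,
    fit_frap,
    pearson_protein_membrane,
    radius_from_integrated_density,
    scaffold_growth_rate,
)
from memtube.synthetic_imaging import (
    RenderConfig,
    ScaffoldSite,
    render_scaffold_tube_pair,
    render_slb,
    render_tube,
    simulate_frap_trace,
    simulate_kymograph,
    simulate_remodeling_movie,
)


@pytest.fixture()
def cfg():
    return RenderConfig(seed=11)


@pytest.fixture()
def quiet_cfg():
    return RenderConfig(seed=11, gain=0.0, read_noise=0.0)


class TestRenderSlb:
    def test_zero_density_background_only(self, quiet_cfg):
        img = render_slb(0.0, (16, 16), quiet_cfg)
        assert np.allclose(img, quiet_cfg.background)

    def test_roi_integrated_density_matches_construction(self, quiet_cfg):
        d = 4.0
        img = render_slb(d, (32, 32), quiet_cfg) - quiet_cfg.background
        roi_sum = img[:10, :10].sum()
        assert roi_sum == pytest.approx(d * (10 * 10) * quiet_cfg.pixel_size**2, rel=1e-12)

    def test_k1_calibration_recovers_density(self, cfg):
        img = render_slb(cfg.brightness, (64, 64), cfg) - cfg.background
        rois = [(2, 2, 10, 10), (20, 20, 20, 20), (40, 8, 16, 24), (8, 40, 12, 12)]
        cal = calibrate_k1(img, rois, cfg.pixel_size)
        assert cal.k1 == pytest.approx(cfg.brightness, rel=0.02)

    def test_generator_deterministic_given_seed(self):
        a = render_slb(3.0, (16, 16), RenderConfig(seed=5))
        b = render_slb(3.0, (16, 16), RenderConfig(seed=5))
        assert np.array_equal(a, b)


class TestRenderTube:
    def test_doubling_radius_doubles_integrated_density(self, quiet_cfg):
        n = 40
        img1 = render_tube(np.full(n, 10.0), quiet_cfg, noise=False) - quiet_cfg.background
        img2 = render_tube(np.full(n, 20.0), quiet_cfg, noise=False) - quiet_cfg.background
        mid = slice(10, 30)  # away from edge effects of the blur
        assert img2[:, mid].sum() == pytest.approx(2.0 * img1[:, mid].sum(), rel=1e-6)

    def test_zero_radius_segment_background_only(self, quiet_cfg):
        r = np.full(60, 12.0)
        r[:20] = 0.0
        img = render_tube(r, quiet_cfg, noise=False)
        assert np.allclose(img[:, :8], quiet_cfg.background, atol=1e-6)

    def test_radius_exceeding_field_rejected(self, quiet_cfg):
        with pytest.raises(ValueError):
            render_tube(np.full(10, 1e5), quiet_cfg)

    def test_k1_route_roundtrip_under_10_percent(self, cfg):
        """Full pipeline: SLB -> k1, tube ID over a segment -> radius,
        recovered within the documented <10% error budget."""
        slb = render_slb(cfg.brightness, (64, 64), cfg) - cfg.background
        k1 = calibrate_k1(
            slb, [(2, 2, 10, 10), (20, 20, 20, 20), (40, 8, 16, 24)], cfg.pixel_size
        ).k1
        for r_true in (8.0, 15.0, 25.0):
            img = render_tube(np.full(60, r_true), cfg) - cfg.background
            seg = img[:, 20:40]
            ID = seg.sum()
            l = 20 * cfg.pixel_size
            r_est = radius_from_integrated_density(ID, l, k1)
            assert abs(r_est - r_true) / r_true < 0.10


class TestRemodelingMovie:
    def _movie(self, seed=3, growth=80.0, n_frames=40):
        cfg = RenderConfig(seed=seed)
        sites = [ScaffoldSite(position=3000.0, nucleation_time=2.0),
                 ScaffoldSite(position=7000.0, nucleation_time=5.0)]
        return simulate_remodeling_movie(
            tube_length=10000.0, baseline_radius=10.0, scaffold_sites=sites,
            growth_rate=growth, fission_radius=5.0, cfg=cfg, n_frames=n_frames,
        )

    def test_zero_growth_static_no_events(self):
        cfg = RenderConfig(seed=4)
        movie, log = simulate_remodeling_movie(
            10000.0, 10.0, [ScaffoldSite(3000.0, 1e9)], 0.0, 5.0, cfg, n_frames=10
        )
        assert log.scission_time is None
        assert log.onsets == {}
        assert np.allclose(log.radius_profiles, 10.0)

    def test_area_conserved_until_scission(self):
        movie, log = self._movie()
        a = log.area_per_frame
        pre = a[~np.isnan(a)]
        assert np.max(np.abs(pre - pre[0]) / pre[0]) < 1e-6

    def test_intermediate_thinning_passes_seven_before_five(self):
        """With baseline 10 nm and threshold 5 nm the far-field radius
        passes through ~7 nm before scission at ~5 nm."""
        movie, log = self._movie(n_frames=80)
        assert log.scission_time is not None
        profs = log.radius_profiles
        far_min = np.nanmin(profs, axis=1)
        pre = far_min[: int(log.scission_time)]
        crossed_7 = np.any((pre < 7.5) & (pre > 6.5))
        assert crossed_7
        last_intact = profs[int(log.scission_time) - 1]
        assert np.nanmin(last_intact) > 4.0

    def test_onset_logged_when_bulge_crosses_threshold(self):
        movie, log = self._movie()
        assert set(log.onsets) == {3000.0, 7000.0}
        assert log.onsets[3000.0] >= 2.0
        assert log.onsets[7000.0] >= 5.0


class TestFrapGenerator:
    def test_immobile_trace_is_flat(self):
        tr = simulate_frap_trace(100.0, 20.0, 0.0, 5.0, noise=0.0)
        assert np.allclose(tr.recovery, 20.0)

    def test_full_recovery_approaches_prebleach(self):
        tr = simulate_frap_trace(100.0, 20.0, 1.0, 2.0, n_points=400,
                                 frame_interval=5.0, noise=0.0)
        assert tr.recovery[-1] == pytest.approx(100.0, rel=0.01)

    def test_fit_recovers_half_mobile_fraction(self):
        errs = []
        for seed in range(20):
            tr = simulate_frap_trace(100.0, 20.0, 0.5, 5.0, seed=seed)
            errs.append(fit_frap(tr).mobile_fraction - 0.5)
        assert np.max(np.abs(errs)) < 0.05

    def test_invalid_mobile_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_frap_trace(100.0, 20.0, 1.5, 5.0)


class TestKymographGenerator:
    def test_zero_speed_vertical_edge(self, cfg):
        kymo = simulate_kymograph(0.0, 10.0, cfg)
        rate = scaffold_growth_rate(kymo, cfg.pixel_size, frame_interval=0.2)
        assert rate.rate == 0.0
        assert rate.low_confidence

    def test_edge_displacement_matches_kinematics(self, quiet_cfg):
        kymo = simulate_kymograph(27.0, 10.0, quiet_cfg)
        thr = 0.5 * (kymo.max() + kymo.min())
        e0 = np.flatnonzero(kymo[0] > thr)[-1]
        e1 = np.flatnonzero(kymo[-1] > thr)[-1]
        dt = (kymo.shape[0] - 1) * 0.2
        assert (e1 - e0) * quiet_cfg.pixel_size == pytest.approx(27.0 * dt, abs=1.2 * quiet_cfg.pixel_size)

    def test_rate_recovery_within_5_percent(self, cfg):
        kymo = simulate_kymograph(27.0, 10.0, cfg)
        rate = scaffold_growth_rate(kymo, cfg.pixel_size, frame_interval=0.2)
        assert rate.rate == pytest.approx(27.0, rel=0.05)


class TestScaffoldSignScenarios:
    def test_bulge_positive_constriction_negative(self):
        cfg = RenderConfig(seed=21)
        mem_b, prot_b = render_scaffold_tube_pair("bulge", cfg)
        mem_c, prot_c = render_scaffold_tube_pair("constriction", RenderConfig(seed=22))
        assert pearson_protein_membrane(prot_b, mem_b) > 0
        assert pearson_protein_membrane(prot_c, mem_c) < 0
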