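"""Trajectory-analysis tests on constructed (noise-free) trajectories:
rigid cylinders, imposed necks, inserted gaps, flipped leaflets."""

import numpy as np
import pytest

from memtube.builder import INNER, OUTER, build_tube
from memtube.cg_model import HEAD, PROTEIN
from memtube.dynamics import Trajectory
from memtube.traj_analysis import (
    detect_scission,
    frame_gaps,
    interleaflet_mixing,
    lumen_radius_profile,
    thinning_timeseries,
)


def cylinder_system(r_in=5.0, length=30.0, seed=0):
    return build_tube(length=length, lumen_diameter=2 * r_in, seed=seed)


def traj_from_frames(system, frames, times=None):
    frames = np.asarray(frames, dtype=np.float32)
    if times is None:
        times = 10000.0 * (np.arange(len(frames)) + 1)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        positions=frames,
        box=system.box.copy(),
        cls=system.cls.copy(),
        lipid_id=system.lipid_id.copy(),
        species=system.species.copy(),
        leaflet=system.leaflet.copy(),
        meta={"system_meta": dict(system.meta)},
    )


@pytest.fixture(scope="module")
def rigid_tube():
    sys_ = cylinder_system()
    return sys_, traj_from_frames(sys_, [sys_.pos.copy() for _ in range(3)])


class TestLumenRadiusProfile:
    def test_rigid_cylinder_recovered_exactly(self, rigid_tube):
        sys_, traj = rigid_tube
        prof = lumen_radius_profile(traj)
        assert np.all(~prof.empty)
        assert np.max(np.abs(prof.mean - 5.0)) < 1e-6
        assert np.max(prof.variance) < 1e-12

    def test_single_bin_is_global_mean(self, rigid_tube):
        sys_, traj = rigid_tube
        prof = lumen_radius_profile(traj, n_bins=1)
        center = np.array([sys_.box[1] / 2, sys_.box[2] / 2])
        inner_heads = (sys_.cls == HEAD) & (sys_.leaflet == INNER)
        r = np.sqrt(np.sum((sys_.pos[inner_heads, 1:] - center) ** 2, axis=1))
        assert prof.mean[0] == pytest.approx(r.mean(), abs=1e-6)

    def test_bin_centers_strictly_increasing(self, rigid_tube):
        prof = lumen_radius_profile(rigid_tube[1])
        assert np.all(np.diff(prof.bin_centers) > 0)

    def test_variance_nonnegative_and_radii_nonnegative(self, rigid_tube):
        prof = lumen_radius_profile(rigid_tube[1])
        assert np.all(prof.variance >= 0)
        assert np.all(prof.mean[~prof.empty] >= 0)


class TestThinningTimeseries:
    def _necked_frames(self, sys_, neck_x, neck_factor, n_frames=4):
        """Scale radial coordinates near neck_x by neck_factor."""
        center = np.array([sys_.box[1] / 2, sys_.box[2] / 2])
        frames = []
        for _ in range(n_frames):
            pos = sys_.pos.copy()
            d = np.abs(pos[:, 0] - neck_x)
            w = np.exp(-0.5 * (d / 2.0) ** 2)
            scale = 1.0 - (1.0 - neck_factor) * w
            pos[:, 1:] = center + (pos[:, 1:] - center) * scale[:, None]
            frames.append(pos)
        return frames

    def test_min_radius_site_at_imposed_neck(self):
        sys_ = cylinder_system()
        neck_x = 22.0
        traj = traj_from_frames(sys_, self._necked_frames(sys_, neck_x, 0.5))
        series = thinning_timeseries(traj, scaffold_boundaries=(13.0, 17.0))
        assert np.all(np.abs(series.thinnest_position - neck_x) < 2.0)
        assert np.all(series.r_thinnest < series.r_middle)

    def test_stationary_series_on_rigid_tube(self, rigid_tube):
        series = thinning_timeseries(rigid_tube[1])
        assert np.ptp(series.r_middle) < 1e-6
        assert np.ptp(series.r_thinnest) < 1e-6
        assert series.fission_frame is None


class TestDetectScission:
    def test_intact_tube_no_fission(self, rigid_tube):
        rec = detect_scission(rigid_tube[1])
        assert not rec.fission
        assert rec.time is None

    def test_inserted_gap_detected_at_frame_and_position(self):
        sys_ = cylinder_system()
        intact = sys_.pos.copy()
        gapped = sys_.pos.copy()
        gap_lo, gap_hi = 12.0, 15.0  # 3 nm lipid-free axial window
        lipids_in_gap = np.unique(
            sys_.lipid_id[(sys_.pos[:, 0] > gap_lo) & (sys_.pos[:, 0] < gap_hi)]
        )
        move = np.isin(sys_.lipid_id, lipids_in_gap)
        gapped[move, 0] = (gapped[move, 0] + 10.0) % sys_.box[0]
        traj = traj_from_frames(sys_, [intact, intact, gapped])
        rec = detect_scission(traj)
        assert rec.fission
        assert rec.frame == 2
        assert gap_lo - 1.0 < rec.position < gap_hi + 1.0
        assert rec.pre_scission_radius == pytest.approx(5.0, abs=0.3)

    def test_gap_reported_by_frame_gaps(self):
        sys_ = cylinder_system()
        gaps = frame_gaps(sys_.pos, sys_.cls, sys_.box)
        assert gaps == []

    def test_lipid_count_conserved_across_analyses(self, rigid_tube):
        sys_, traj = rigid_tube
        n = sys_.n_lipids
        _, frac = interleaflet_mixing(traj)
        # mixing returns fractions over exactly n lipids each frame
        assert np.all((frac * n) == np.round(frac * n))


class TestInterleafletMixing:
    def test_static_tube_no_mixing(self, rigid_tube):
        _, frac = interleaflet_mixing(rigid_tube[1])
        assert np.all(frac == 0.0)

    def test_flipped_lipids_counted_exactly(self):
        sys_ = cylinder_system()
        center = np.array([sys_.box[1] / 2, sys_.box[2] / 2])
        flipped = sys_.pos.copy()
        k = 17
        outer_ids = np.unique(sys_.lipid_id[(sys_.leaflet == OUTER) & (sys_.cls != PROTEIN)])[:k]
        sel = np.isin(sys_.lipid_id, outer_ids)
        # reflect the flipped lipids' sites about their head radius so the
        # head now points inward (head-body radial component changes sign)
        for lid in outer_ids:
            sites = np.flatnonzero(sys_.lipid_id == lid)
            order = np.argsort(sys_.cls[sites])
            h, b, t = sites[order]
            for s in (b, t):
                d = flipped[s, 1:] - center
                dh = flipped[h, 1:] - center
                rh = np.linalg.norm(dh)
                rs = np.linalg.norm(d)
                flipped[s, 1:] = center + d / rs * (2 * rh - rs)
        traj = traj_from_frames(sys_, [sys_.pos.copy(), flipped])
        _, frac = interleaflet_mixing(traj)
        assert frac[0] == 0.0
        assert frac[1] == pytest.approx(k / sys_.n_lipids, abs=1e-12)
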