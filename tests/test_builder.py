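"""Builder tests: printed geometry numbers, leaflet bookkeeping,
scaffold ring arithmetic, determinism."""

import numpy as np
import pytest

from memtube.builder import (
    DOPS,
    GeometryError,
    INNER,
    OUTER,
    build_bare_tube_series,
    build_patch,
    build_scaffold,
    build_tube,
    place_scaffold,
    ring_site_spacing,
)
from memtube.cg_model import PROTEIN, LipidParams


class TestRingGeometry:
    def test_reference_ring_spacing(self):
        # 35 sites on a 25 nm ring sit 2.24 nm apart (chord of 2 pi/35)
        assert ring_site_spacing(25.0, 35) == pytest.approx(2.24, abs=0.005)

    def test_two_sites_are_antipodal(self):
        assert ring_site_spacing(17.3, 2) == pytest.approx(17.3)

    def test_chord_formula_four_sites(self):
        assert ring_site_spacing(25.0, 4) == pytest.approx(25.0 * np.sin(np.pi / 4), rel=1e-12)

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValueError):
            ring_site_spacing(25.0, 1)


class TestBuildScaffold:
    @pytest.mark.parametrize("length,n_sites", [(4.0, 560), (20.0, 2800)])
    def test_reference_site_counts(self, length, n_sites):
        s = build_scaffold(length, axial_center=50.0)
        assert s.n_sites == n_sites
        assert s.site_positions.shape == (n_sites, 3)

    def test_single_ring(self):
        s = build_scaffold(0.25, axial_center=10.0)
        assert s.n_rings == 1
        assert s.n_sites == 35

    def test_all_sites_on_ring_radius(self):
        s = build_scaffold(4.0, axial_center=50.0)
        r = np.sqrt(s.site_positions[:, 1] ** 2 + s.site_positions[:, 2] ** 2)
        assert np.max(np.abs(r - 12.5)) < 1e-9

    def test_in_ring_spacing_constant(self):
        s = build_scaffold(0.25, axial_center=10.0)
        p = s.site_positions
        d = np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1)
        assert np.ptp(d) < 1e-9
        assert d[0] == pytest.approx(ring_site_spacing(25.0, 35), rel=1e-9)

    def test_too_short_scaffold_rejected(self):
        with pytest.raises(ValueError):
            build_scaffold(0.1, ring_spacing=0.25)


class TestBuildTube:
    def test_reference_site_count(self):
        # full-scale reference: 14,500 lipids -> 43,500 lipid CG sites
        sys_ = build_tube(length=100.0, lumen_diameter=11.0, outer_diameter=20.0,
                          n_lipids=14500, seed=0)
        assert sys_.n_sites == 43500
        assert sys_.n_lipids == 14500

    def test_ps_fraction_count(self):
        sys_ = build_tube(length=100.0, lumen_diameter=11.0, outer_diameter=20.0,
                          n_lipids=14500, ps_fraction=0.40, seed=0)
        n_ps = int(np.sum(sys_.species[sys_.cls != PROTEIN] == DOPS)) // 3
        assert n_ps == 5800

    def test_geometric_area_per_lipid(self):
        # 100 nm tube, head radii 10.0/5.5 nm, 14,500 lipids -> ~0.67 nm^2
        apl = 2 * np.pi * 100.0 * (10.0 + 5.5) / 14500
        assert apl == pytest.approx(0.67, abs=0.005)
        sys_ = build_tube(length=100.0, lumen_diameter=11.0, outer_diameter=20.0, seed=0)
        implied = 2 * np.pi * 100.0 * (10.0 + 5.5) / sys_.n_lipids
        assert implied == pytest.approx(sys_.meta["apl_target"], rel=0.02)

    def test_leaflet_counts_proportional_to_midsurface_areas(self):
        params = LipidParams()
        sys_ = build_tube(length=30.0, lumen_diameter=6.0, seed=3, params=params)
        b = params.bond_length
        r_in, r_out = sys_.meta["lumen_radius"], sys_.meta["outer_radius"]
        n_out = len(np.unique(sys_.lipid_id[sys_.leaflet == OUTER]))
        n_in = len(np.unique(sys_.lipid_id[sys_.leaflet == INNER]))
        expect = sys_.n_lipids * (r_out - b) / ((r_out - b) + (r_in + b))
        assert abs(n_out - expect) <= 1.0

    def test_deterministic_given_seed(self):
        a = build_tube(length=30.0, lumen_diameter=5.0, seed=7)
        b = build_tube(length=30.0, lumen_diameter=5.0, seed=7)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.species, b.species)

    def test_seed_scrambles_species_and_placement_only(self):
        a = build_tube(length=30.0, lumen_diameter=5.0, seed=7)
        b = build_tube(length=30.0, lumen_diameter=5.0, seed=8)
        assert a.n_sites == b.n_sites
        assert not np.array_equal(a.pos, b.pos)
        assert not np.array_equal(a.species, b.species)
        assert np.array_equal(a.cls, b.cls)
        assert np.array_equal(a.leaflet, b.leaflet)

    def test_no_overlapping_sites(self):
        sys_ = build_tube(length=30.0, lumen_diameter=5.5, seed=1)
        assert sys_.min_pair_distance() > 0.45

    def test_negative_lumen_rejected(self):
        with pytest.raises(GeometryError):
            build_tube(length=30.0, lumen_diameter=-2.0)

    def test_incompatible_lipid_count_warns(self):
        with pytest.warns(UserWarning):
            build_tube(length=30.0, lumen_diameter=5.5, n_lipids=400, seed=0)

    def test_every_lipid_has_three_sites(self):
        sys_ = build_tube(length=30.0, lumen_diameter=5.5, seed=1)
        _, counts = np.unique(sys_.lipid_id, return_counts=True)
        assert np.all(counts == 3)


class TestBareTubeSeries:
    def test_series_length_and_apl(self):
        systems = build_bare_tube_series(np.arange(2.0, 10.1, 1.0), length=30.0)
        assert len(systems) == 9
        for sys_ in systems:
            r_in, r_out = sys_.meta["lumen_radius"], sys_.meta["outer_radius"]
            apl = 2 * np.pi * 30.0 * (r_in + r_out) / sys_.n_lipids
            assert apl == pytest.approx(sys_.meta["apl_target"], rel=0.02)

    def test_zero_diameter_rejected(self):
        with pytest.raises(GeometryError):
            build_bare_tube_series([4.0, 0.0], length=30.0)


class TestPlaceScaffold:
    def _tube(self):
        return build_tube(length=30.0, lumen_diameter=5.5, seed=1)

    def test_frozen_count_increases_by_scaffold_sites(self):
        sys_ = self._tube()
        ring_d = 2 * (sys_.meta["outer_radius"] + 1.5)
        sc = build_scaffold(3.0, ring_diameter=ring_d, axial_center=15.0)
        out = place_scaffold(sys_, sc)
        assert int(np.sum(out.frozen)) == sc.n_sites
        assert out.n_free == sys_.n_free
        assert np.array_equal(out.pos[: sys_.n_sites], sys_.pos)

    def test_scaffold_sites_at_ring_radius(self):
        sys_ = self._tube()
        ring_d = 2 * (sys_.meta["outer_radius"] + 1.5)
        sc = build_scaffold(3.0, ring_diameter=ring_d, axial_center=15.0)
        out = place_scaffold(sys_, sc)
        center = np.array([out.box[1] / 2, out.box[2] / 2])
        r = np.linalg.norm(out.pos[out.frozen][:, 1:] - center, axis=1)
        assert np.max(np.abs(r - ring_d / 2)) < 1e-9

    def test_scaffold_outside_box_rejected(self):
        sys_ = self._tube()
        ring_d = 2 * (sys_.meta["outer_radius"] + 1.5)
        sc = build_scaffold(3.0, ring_diameter=ring_d, axial_center=29.5)
        with pytest.raises(GeometryError):
            place_scaffold(sys_, sc)

    def test_ring_smaller_than_tube_rejected(self):
        sys_ = self._tube()
        sc = build_scaffold(3.0, ring_diameter=2.0, axial_center=15.0)
        with pytest.raises(GeometryError):
            place_scaffold(sys_, sc)


class TestBuildPatch:
    def test_patch_has_two_equal_leaflets(self):
        p = build_patch(12.0, 12.0, seed=0)
        n_out = len(np.unique(p.lipid_id[p.leaflet == OUTER]))
        n_in = len(np.unique(p.lipid_id[p.leaflet == INNER]))
        assert n_out == n_in
        assert p.n_lipids == n_out + n_in

    def test_patch_apl_matches_target(self):
        p = build_patch(12.0, 12.0, seed=0, apl=0.7)
        apl = 2 * 12.0 * 12.0 / p.n_lipids
        assert apl == pytest.approx(0.7, rel=0.02)
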