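"""Construction of initial conditions: bilayer tubes, planar patches, and
frozen ring scaffolds in a periodic box.

Geometry conventions
--------------------
The tube axis is x; the box is periodic in all three dimensions and the
tube is continuous through its periodic image in x.  The "lumen radius"
is measured to inner-leaflet head-site centers, so a requested lumen
diameter of 11 nm places inner heads at radius 5.5 nm.  Lipids are laid
out on two concentric cylindrical lattices (leaflets) with tails pointing
toward the bilayer midplane; leaflet lipid counts are proportional to the
leaflet mid-surface areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import BODY, HEAD, PROTEIN, TAIL, LipidParams

DOPC, DOPS = 0, 1
OUTER, INNER, NO_LEAFLET = 0, 1, -1


class GeometryError(ValueError):
    """Raised for infeasible build geometry."""


@dataclass
class SimulationSystem:
    """Positions, labels, and box of a built system.

    Lipid sites come first (three consecutive sites head/body/tail per
    lipid, sharing a ``lipid_id``), followed by frozen protein sites.
    ``frozen`` is true exactly for protein-class sites.
    """

    box: np.ndarray                  # (3,) nm
    pos: np.ndarray                  # (N, 3) nm
    vel: np.ndarray                  # (N, 3)
    cls: np.ndarray                  # (N,) int8: HEAD/BODY/TAIL/PROTEIN
    lipid_id: np.ndarray             # (N,) int32, -1 for protein sites
    species: np.ndarray              # (N,) int8: DOPC/DOPS, -1 for protein
    leaflet: np.ndarray              # (N,) int8: OUTER/INNER, -1 for protein
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_free(self) -> int:
        return int(np.sum(self.cls != PROTEIN))

    @property
    def n_lipids(self) -> int:
        return self.n_free // 3

    @property
    def frozen(self) -> np.ndarray:
        return self.cls == PROTEIN

    def copy(self) -> "SimulationSystem":
        return SimulationSystem(
            box=self.box.copy(),
            pos=self.pos.copy(),
            vel=self.vel.copy(),
            cls=self.cls.copy(),
            lipid_id=self.lipid_id.copy(),
            species=self.species.copy(),
            leaflet=self.leaflet.copy(),
            meta=dict(self.meta),
        )

    def validate(self) -> None:
        n = self.n_sites
        for name in ("pos", "vel"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape (N, 3)")
        if np.any(self.pos < -1e-9) or np.any(self.pos > self.box[None, :] + 1e-9):
            raise ValueError("all positions must lie inside the box")
        lipid_sites = self.cls != PROTEIN
        ids = self.lipid_id[lipid_sites]
        if ids.size % 3 != 0:
            raise ValueError("every lipid must have exactly 3 sites")
        uniq, counts = np.unique(ids, return_counts=True)
        if np.any(counts != 3):
            raise ValueError("every lipid must have exactly 3 sites")
        if np.any(self.lipid_id[~lipid_sites] != -1):
            raise ValueError("protein sites carry no lipid id")
        if np.any(self.leaflet[lipid_sites] == NO_LEAFLET):
            raise ValueError("leaflet labels must partition lipids")

    def min_pair_distance(self) -> float:
        """Minimum inter-site distance excluding intra-lipid pairs (nm)."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.pos, boxsize=self.box)
        dists, idx = tree.query(self.pos, k=5)
        best = np.inf
        for i in range(self.n_sites):
            for d, j in zip(dists[i][1:], idx[i][1:]):
                if self.lipid_id[i] >= 0 and self.lipid_id[i] == self.lipid_id[j]:
                    continue
                if self.cls[i] == PROTEIN and self.cls[j] == PROTEIN:
                    continue
                best = min(best, d)
                break
        return float(best)


@dataclass
class Scaffold:
    """Stacked rings of frozen attractive protein sites around the tube axis.

    Defaults follow the scaffold used for the full-scale systems: ring
    diameter 25 nm, 35 sites per ring, rings 0.25 nm apart axially.
    """

    ring_diameter: float = 25.0
    sites_per_ring: int = 35
    ring_spacing: float = 0.25
    scaffold_length: float = 4.0
    axial_center: float = 50.0
    staggered: bool = False
    site_positions: np.ndarray = None  # (M, 3), axis = x through (0, 0)

    def __post_init__(self):
        if self.sites_per_ring < 3:
            raise ValueError("sites_per_ring must be >= 3")
        if self.scaffold_length < self.ring_spacing:
            raise ValueError("scaffold_length must be >= ring_spacing")
        if self.site_positions is None:
            self.site_positions = self._build_sites()

    @property
    def n_rings(self) -> int:
        return int(round(self.scaffold_length / self.ring_spacing))

    @property
    def n_sites(self) -> int:
        return self.n_rings * self.sites_per_ring

    @property
    def boundaries(self) -> tuple[float, float]:
        """Axial extent (nm) of the scaffold, centered on ``axial_center``."""
        half = 0.5 * self.scaffold_length
        return (self.axial_center - half, self.axial_center + half)

    def _build_sites(self) -> np.ndarray:
        r = 0.5 * self.ring_diameter
        nr = self.n_rings
        span = (nr - 1) * self.ring_spacing
        xs = self.axial_center - 0.5 * span + self.ring_spacing * np.arange(nr)
        theta0 = np.zeros(nr)
        if self.staggered:
            theta0 = (np.arange(nr) % 2) * (np.pi / self.sites_per_ring)
        theta = 2.0 * np.pi * np.arange(self.sites_per_ring) / self.sites_per_ring
        out = np.empty((nr * self.sites_per_ring, 3))
        k = 0
        for i in range(nr):
            for t in theta + theta0[i]:
                out[k] = (xs[i], r * np.cos(t), r * np.sin(t))
                k += 1
        return out


def ring_site_spacing(ring_diameter: float, sites_per_ring: int) -> float:
    """Center-to-center spacing of adjacent sites on one ring (chord, nm)."""
    if sites_per_ring < 2:
        raise ValueError("sites_per_ring must be >= 2")
    if ring_diameter <= 0:
        raise GeometryError("ring_diameter must be > 0")
    return float(ring_diameter * np.sin(np.pi / sites_per_ring))


def build_scaffold(
    scaffold_length: float,
    ring_diameter: float = 25.0,
    sites_per_ring: int = 35,
    ring_spacing: float = 0.25,
    axial_center: float = 50.0,
    staggered: bool = False,
) -> Scaffold:
    """Build a ring-stack scaffold of the given axial length.

    The number of rings is round(scaffold_length / ring_spacing), so a
    4 nm scaffold at 0.25 nm spacing has 16 rings = 560 sites and a 20 nm
    scaffold has 80 rings = 2800 sites.
    """
    return Scaffold(
        ring_diameter=ring_diameter,
        sites_per_ring=sites_per_ring,
        ring_spacing=ring_spacing,
        scaffold_length=scaffold_length,
        axial_center=axial_center,
        staggered=staggered,
    )


# ----------------------------------------------------------------------
# lipid lattices
# ----------------------------------------------------------------------

def _cylinder_lattice(n: int, radius: float, length: float, rng) -> np.ndarray:
    """(x, theta) lattice of n points on a cylinder surface, lightly jittered."""
    if n < 1:
        raise GeometryError("leaflet with no lipids")
    circ = 2.0 * np.pi * radius
    n_rows = max(1, int(round(np.sqrt(n * length / circ))))
    base = n // n_rows
    extra = n % n_rows
    dx = length / n_rows
    pts = np.empty((n, 2))
    k = 0
    for row in range(n_rows):
        m = base + (1 if row < extra else 0)
        x = (row + 0.5) * dx
        off = rng.uniform(0.0, 2.0 * np.pi)
        for i in range(m):
            th = off + 2.0 * np.pi * i / m
            pts[k] = (x + rng.uniform(-0.05, 0.05) * dx, th)
            k += 1
    return pts


def _place_lipids(
    sys_pos, sys_cls, sys_lid, sys_leaf, start_site, start_lid,
    lattice, radius, leaflet, bond, center_yz, length,
):
    """Write head/body/tail sites for one leaflet; tails point to midplane."""
    sgn = -1.0 if leaflet == OUTER else +1.0  # radial direction of the tail
    k = start_site
    lid = start_lid
    for x, th in lattice:
        c, s = np.cos(th), np.sin(th)
        for depth, cl in ((0.0, HEAD), (1.0, BODY), (2.0, TAIL)):
            r = radius + sgn * depth * bond
            sys_pos[k] = (x % length, center_yz[0] + r * c, center_yz[1] + r * s)
            sys_cls[k] = cl
            sys_lid[k] = lid
            sys_leaf[k] = leaflet
            k += 1
        lid += 1
    return k, lid


def build_tube(
    length: float,
    lumen_diameter: float,
    outer_diameter: float | None = None,
    n_lipids: int | None = None,
    ps_fraction: float = 0.40,
    seed: int = 0,
    params: LipidParams | None = None,
    apl: float | None = None,
    box_margin: float = 6.0,
) -> SimulationSystem:
    """Build a bilayer tube spanning the periodic box along x.

    Parameters mirror the full-scale reference system: a 100 nm tube with
    outer diameter 20 nm, lumen diameter ~11 nm and 14,500 lipids (43,500
    lipid sites) at 40:60 DOPS:DOPC.  If ``n_lipids`` is omitted it is
    chosen from the target area per lipid applied to the two head
    surfaces; if ``outer_diameter`` is omitted it follows from the lumen
    diameter plus twice the geometric leaflet thickness.
    """
    params = params or LipidParams()
    apl = apl if apl is not None else params.target_apl
    r_in = 0.5 * lumen_diameter
    if r_in <= 0:
        raise GeometryError("lumen diameter must be > 0")
    thickness = params.geometric_thickness()
    if outer_diameter is None:
        r_out = r_in + thickness
    else:
        r_out = 0.5 * outer_diameter
        if abs((r_out - r_in) - thickness) > 0.35 * thickness:
            warnings.warn(
                "outer/lumen diameters imply a bilayer thickness of "
                f"{r_out - r_in:.2f} nm vs the model's {thickness:.2f} nm",
                stacklevel=2,
            )
    if r_out <= r_in:
        raise GeometryError("outer radius must exceed lumen radius")

    area_heads = 2.0 * np.pi * length * (r_in + r_out)
    n_auto = int(round(area_heads / apl))
    if n_lipids is None:
        n_lipids = n_auto
    else:
        implied_apl = area_heads / n_lipids
        if not (0.5 * apl <= implied_apl <= 2.0 * apl):
            warnings.warn(
                f"n_lipids={n_lipids} implies area per lipid {implied_apl:.3f} nm^2, "
                f"far from the {apl:.3f} nm^2 target",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    b = params.bond_length
    # leaflet split proportional to mid-surface (body-site) areas
    r_mid_out = r_out - b
    r_mid_in = r_in + b
    n_outer = int(round(n_lipids * r_mid_out / (r_mid_out + r_mid_in)))
    n_inner = n_lipids - n_outer
    if n_inner < 1 or n_outer < 1:
        raise GeometryError("geometry leaves a leaflet empty")

    box = np.array([length, 2.0 * (r_out + box_margin), 2.0 * (r_out + box_margin)])
    center = (0.5 * box[1], 0.5 * box[2])

    n_sites = 3 * n_lipids
    pos = np.empty((n_sites, 3))
    cls = np.empty(n_sites, dtype=np.int8)
    lid = np.empty(n_sites, dtype=np.int32)
    leaf = np.empty(n_sites, dtype=np.int8)

    lat_out = _cylinder_lattice(n_outer, r_out, length, rng)
    lat_in = _cylinder_lattice(n_inner, r_in, length, rng)
    k, next_lid = _place_lipids(pos, cls, lid, leaf, 0, 0, lat_out, r_out, OUTER, b, center, length)
    k, next_lid = _place_lipids(pos, cls, lid, leaf, k, next_lid, lat_in, r_in, INNER, b, center, length)

    species_site = np.empty(n_sites, dtype=np.int8)
    per_lipid = np.full(n_lipids, DOPC, dtype=np.int8)
    n_ps = int(round(ps_fraction * n_lipids))
    per_lipid[rng.permutation(n_lipids)[:n_ps]] = DOPS
    species_site[:] = np.repeat(per_lipid, 3)

    sys = SimulationSystem(
        box=box,
        pos=pos,
        vel=np.zeros_like(pos),
        cls=cls,
        lipid_id=lid,
        species=species_site,
        leaflet=leaf,
        meta={
            "kind": "tube",
            "length": length,
            "lumen_radius": r_in,
            "outer_radius": r_out,
            "ps_fraction": ps_fraction,
            "apl_target": apl,
            "seed": int(seed),
        },
    )
    sys.validate()
    return sys


def build_bare_tube_series(
    lumen_diameters,
    length: float,
    ps_fraction: float = 0.40,
    seed: int = 0,
    params: LipidParams | None = None,
    apl: float | None = None,
) -> list[SimulationSystem]:
    """One bare tube per lumen diameter, lipid counts rescaled so the
    geometric area per lipid stays fixed across the series."""
    out = []
    for i, d in enumerate(lumen_diameters):
        if d <= 0:
            raise GeometryError("lumen diameter must be > 0")
        out.append(
            build_tube(
                length=length,
                lumen_diameter=d,
                ps_fraction=ps_fraction,
                seed=seed + i,
                params=params,
                apl=apl,
            )
        )
    return out


def build_patch(
    lx: float,
    ly: float,
    seed: int = 0,
    params: LipidParams | None = None,
    apl: float | None = None,
    ps_fraction: float = 0.40,
    box_margin: float = 5.0,
) -> SimulationSystem:
    """Planar bilayer patch in the x-y plane (midplane at z = box_z/2).

    Used for emergent-property checks (thickness, stability) of the lipid
    model; the patch spans the periodic box in x and y.
    """
    params = params or LipidParams()
    apl = apl if apl is not None else params.target_apl
    rng = np.random.default_rng(seed)
    b = params.bond_length
    n_per_leaf = int(round(lx * ly / apl))
    half_t = 0.5 * params.geometric_thickness()
    box = np.array([lx, ly, 2.0 * (half_t + box_margin)])
    z_mid = 0.5 * box[2]

    n_lipids = 2 * n_per_leaf
    n_sites = 3 * n_lipids
    pos = np.empty((n_sites, 3))
    cls = np.empty(n_sites, dtype=np.int8)
    lid = np.empty(n_sites, dtype=np.int32)
    leaf = np.empty(n_sites, dtype=np.int8)

    k = 0
    next_lid = 0
    for leaflet, sgn in ((OUTER, +1.0), (INNER, -1.0)):
        n_rows = max(1, int(round(np.sqrt(n_per_leaf * ly / lx))))
        base, extra = divmod(n_per_leaf, n_rows)
        dy = ly / n_rows
        for row in range(n_rows):
            m = base + (1 if row < extra else 0)
            y = (row + 0.5) * dy
            xoff = rng.uniform(0, lx)
            for i in range(m):
                x = (xoff + lx * i / m) % lx
                z_head = z_mid + sgn * half_t
                for depth, cl in ((0.0, HEAD), (1.0, BODY), (2.0, TAIL)):
                    pos[k] = (x, y, z_head - sgn * depth * b)
                    cls[k] = cl
                    lid[k] = next_lid
                    leaf[k] = leaflet
                    k += 1
                next_lid += 1

    species_site = np.empty(n_sites, dtype=np.int8)
    per_lipid = np.full(n_lipids, DOPC, dtype=np.int8)
    n_ps = int(round(ps_fraction * n_lipids))
    per_lipid[rng.permutation(n_lipids)[:n_ps]] = DOPS
    species_site[:] = np.repeat(per_lipid, 3)

    sys = SimulationSystem(
        box=box,
        pos=pos,
        vel=np.zeros_like(pos),
        cls=cls,
        lipid_id=lid,
        species=species_site,
        leaflet=leaf,
        meta={"kind": "patch", "lx": lx, "ly": ly, "apl_target": apl, "seed": int(seed)},
    )
    sys.validate()
    return sys


def place_scaffold(
    system: SimulationSystem,
    scaffold: Scaffold,
    min_clearance: float = 0.2,
) -> SimulationSystem:
    """Append the scaffold's sites to the system as frozen protein sites.

    The scaffold must be coaxial with the tube, lie within the box along
    x, and its ring radius must exceed the tube's outer radius.  Lipid
    positions are untouched.  Raises if any protein site would start
    closer than ``min_clearance`` to a lipid site.
    """
    lo, hi = scaffold.boundaries
    if lo < 0 or hi > system.box[0]:
        raise GeometryError(
            f"scaffold axial extent [{lo:.2f}, {hi:.2f}] nm exceeds the box "
            f"(0, {system.box[0]:.2f})"
        )
    r_ring = 0.5 * scaffold.ring_diameter
    r_out = system.meta.get("outer_radius")
    if r_out is not None and r_ring <= r_out:
        raise GeometryError(
            f"ring radius {r_ring:.2f} nm must exceed the tube outer radius {r_out:.2f} nm"
        )

    center = np.array([0.0, 0.5 * system.box[1], 0.5 * system.box[2]])
    ppos = scaffold.site_positions + center[None, :]

    from scipy.spatial import cKDTree

    tree = cKDTree(system.pos, boxsize=system.box)
    d, _ = tree.query(ppos % system.box[None, :], k=1)
    if np.min(d) < min_clearance:
        raise GeometryError(
            f"a scaffold site starts {np.min(d):.3f} nm from a lipid site "
            f"(< {min_clearance} nm); enlarge the ring or re-center the scaffold"
        )

    m = ppos.shape[0]
    out = SimulationSystem(
        box=system.box.copy(),
        pos=np.vstack([system.pos, ppos % system.box[None, :]]),
        vel=np.vstack([system.vel, np.zeros((m, 3))]),
        cls=np.concatenate([system.cls, np.full(m, PROTEIN, dtype=np.int8)]),
        lipid_id=np.concatenate([system.lipid_id, np.full(m, -1, dtype=np.int32)]),
        species=np.concatenate([system.species, np.full(m, -1, dtype=np.int8)]),
        leaflet=np.concatenate([system.leaflet, np.full(m, NO_LEAFLET, dtype=np.int8)]),
        meta=dict(system.meta),
    )
    out.meta["scaffold_boundaries"] = scaffold.boundaries
    out.meta["scaffold_ring_radius"] = r_ring
    out.validate()
    return out
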