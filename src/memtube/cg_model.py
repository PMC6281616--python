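"""Coarse-grained force field for three-site lipids and frozen protein scaffolds.

The membrane model is a solvent-free three-site lipid (head--body--tail)
with soft repulsive cores and a broad, finite-range attractive well
between the hydrophobic site classes (body, tail) — the structure of
effective potentials obtained by force-matching highly coarse-grained
membrane models.  The parameters shipped here are tuned so that a
bilayer is fluid and stable at 310 K with a head-to-head thickness
in the 4-5 nm range at an area per lipid near 0.7 nm^2, while keeping
topological rearrangements (flip-flop, scission of thin necks)
thermally accessible.

Protein scaffold sites interact with lipid *head* sites only, through a
12-6 Lennard-Jones potential (sigma = 0.2 nm, epsilon = 1 kcal/mol),
energy-shifted to zero at the cutoff.  Scaffold sites are frozen and do
not interact with each other.

Units
-----
length      nm
energy      kcal/mol
mass        1 per site (reduced)
temperature K  (kB = 1.987204e-3 kcal/mol/K)
time        the internal unit is t0 = sqrt(mass * nm^2 / (kcal/mol));
            the CG time unit tau used in run protocols is defined as the
            default integrator step, tau = 0.01 t0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# Boltzmann constant, kcal/mol/K
KB = 1.987204259e-3

# CG time unit tau expressed in internal time units; the default
# integrator step is exactly 1 tau.
TAU = 0.01

# site class codes
HEAD, BODY, TAIL, PROTEIN = 0, 1, 2, 3
CLASS_NAMES = ("head", "body", "tail", "protein")

_CLASS_INDEX = {"head": HEAD, "body": BODY, "tail": TAIL}


def _as_class(c) -> int:
    if isinstance(c, str):
        return _CLASS_INDEX[c.lower()]
    c = int(c)
    if c not in (HEAD, BODY, TAIL):
        raise ValueError(f"not a lipid site class: {c}")
    return c


@dataclass
class LipidParams:
    """Pair-interaction tables for the lipid site classes {head, body, tail}.

    The repulsive core is *soft*: a smooth barrier of height ``eps_rep``
    (kcal/mol) reaching zero, with zero force, at the range parameter
    r0 = 2^(1/6) sigma:

        V_rep(r) = eps_rep * (1 - (r/r0)^2)^2,   r < r0.

    Soft cores are the signature of effective potentials derived by
    force-matching ultra-coarse models: lipid passage costs a finite
    (~10-25 kT) barrier rather than being excluded, which keeps the
    bilayer intact at 310 K while leaving topological rearrangements
    (flip-flop, stalk formation, scission) thermally accessible — the
    regime in which membrane tubes remodel on simulated timescales.

    ``well_depth`` and ``well_width`` parameterize the attractive well
    acting between hydrophobic (body/tail) pairs, and optionally between
    head pairs (headgroup bridging of apposed membranes).  The well is
    flat at ``-well_depth`` up to r0 and decays to zero at r0 +
    well_width with continuous energy and force:

        V_att(r) = -eps * (1 - u^2)^2,   u = (r^2 - r0^2) / (rc^2 - r0^2)

    the same qualitative shape as the cosine-squared well of Cooke-type
    models but polynomial in r^2.

    Bonds within a lipid (head-body, body-tail) are harmonic springs of
    rest length ``bond_length``; a softer 1-3 spring between head and
    tail (rest length 2*bond_length) keeps the lipid straight.
    """

    # core range parameters (nm) per class pair; heads are smaller than
    # the hydrophobic sites (cone-shaped lipids), which favours
    # self-assembly into bilayers and negative-curvature intermediates.
    sigma: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.68, 0.74, 0.74],
                [0.74, 0.80, 0.80],
                [0.74, 0.80, 0.80],
            ]
        )
    )
    # soft-core barrier height (kcal/mol)
    eps_rep: np.ndarray = field(default_factory=lambda: np.full((3, 3), 15.0))
    # attractive well depth (kcal/mol); hydrophobic cohesion (a head-head
    # term for headgroup bridging is supported but off by default)
    well_depth: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.65, 0.65],
                [0.0, 0.65, 0.65],
            ]
        )
    )
    # attractive well width w_c (nm): cutoff = 2^(1/6) sigma + w_c
    well_width: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 1.30, 1.30],
                [0.0, 1.30, 1.30],
            ]
        )
    )
    # intra-lipid bonded terms
    bond_length: float = 1.00          # nm, head-body and body-tail
    bond_k: float = 100.0              # kcal/mol/nm^2
    straight_k: float = 5.0            # kcal/mol/nm^2, head-tail 1-3 spring

    # per-species scale on the head-head repulsion strength (config hook
    # for DOPS vs DOPC; identical by default -- species are bookkeeping
    # labels unless this is changed)
    dops_head_scale: float = 1.0
    dopc_head_scale: float = 1.0

    # target emergent observables (for reporting/tests, not fit at runtime)
    target_thickness: float = 5.0      # nm, bilayer head-to-head
    target_apl: float = 0.67           # nm^2, area per lipid

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.eps_rep = np.asarray(self.eps_rep, dtype=float)
        self.well_depth = np.asarray(self.well_depth, dtype=float)
        self.well_width = np.asarray(self.well_width, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in ("sigma", "eps_rep", "well_depth", "well_width"):
            m = getattr(self, name)
            if m.shape != (3, 3):
                raise ValueError(f"{name} must be a 3x3 table")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} table must be symmetric")
        if np.any(self.sigma <= 0):
            raise ValueError("all range parameters must be > 0")
        if np.any(self.eps_rep <= 0):
            raise ValueError("all repulsion strengths must be > 0")
        if np.any(self.well_depth < 0) or np.any(self.well_width < 0):
            raise ValueError("well depth/width must be >= 0")
        if self.bond_length <= 0 or self.bond_k <= 0 or self.straight_k < 0:
            raise ValueError("bond parameters must be positive")
        if np.any(self.cutoff() < self.r_min()):
            raise ValueError("cutoffs must not be below the core minimum")
        # implementation constraints of the fast pair kernels: head-to-
        # hydrophobic pairs are repulsive-only (head-head attraction is
        # allowed — it models headgroup bridging of apposed membranes),
        # and the hydrophobic (body/tail) block shares one parameter set
        if (
            self.well_depth[0, 1] != 0.0
            or self.well_depth[0, 2] != 0.0
            or self.well_depth[1, 0] != 0.0
            or self.well_depth[2, 0] != 0.0
        ):
            raise ValueError("head-to-body/tail pairs must have zero well depth")
        for name in ("sigma", "eps_rep", "well_depth", "well_width"):
            blk = getattr(self, name)[1:, 1:]
            if not np.all(blk == blk[0, 0]):
                raise ValueError(
                    f"{name}: body/tail classes must share one parameter value"
                )

    # derived geometry ---------------------------------------------------
    def r_min(self) -> np.ndarray:
        """Position of the WCA core edge / attractive-well minimum, per pair."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    def cutoff(self) -> np.ndarray:
        """Interaction cutoff per class pair (nm)."""
        return self.r_min() + self.well_width

    @property
    def max_cutoff(self) -> float:
        return float(self.cutoff().max())

    def geometric_thickness(self) -> float:
        """Head-to-head bilayer thickness implied by the builder geometry (nm)."""
        return 4.0 * self.bond_length + self.sigma[TAIL, TAIL]

    # serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("sigma", "eps_rep", "well_depth", "well_width"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LipidParams":
        return cls(**d)


@dataclass
class ProteinLipidPotential:
    """12-6 Lennard-Jones attraction between scaffold sites and lipid heads.

    Energy-shifted so the potential is exactly zero at the cutoff.  The
    default cutoff of 2.5 sigma follows the convention for truncated LJ;
    desk-scale presets widen it (see :mod:`memtube.presets`) so that the
    attraction band around a scaled-down ring remains within reach of
    thermal membrane undulations.
    """

    sigma: float = 0.2      # nm
    epsilon: float = 1.0    # kcal/mol
    cutoff: float = 0.5     # nm (= 2.5 sigma for the defaults)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.cutoff <= self.sigma:
            raise ValueError("cutoff must exceed sigma")

    @property
    def r_min(self) -> float:
        """Position of the LJ minimum, 2^(1/6) sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def shift(self) -> float:
        """Energy of the unshifted LJ at the cutoff (subtracted inside it)."""
        sr6 = (self.sigma / self.cutoff) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


# ----------------------------------------------------------------------
# reference (non-vectorized-kernel) energy and force evaluations
# ----------------------------------------------------------------------

def _check_distance(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be > 0")
    return r


def lipid_pair_energy(site_class_i, site_class_j, distance, params: LipidParams):
    """Nonbonded pair energy between two lipid sites (kcal/mol).

    Sum of the WCA core and, for hydrophobic pairs, the attractive well.
    Zero at and beyond the pair cutoff; energy and force are continuous
    everywhere on (0, cutoff].
    """
    ci, cj = _as_class(site_class_i), _as_class(site_class_j)
    r = _check_distance(distance)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)

    sig = params.sigma[ci, cj]
    eps = params.eps_rep[ci, cj]
    r0 = 2.0 ** (1.0 / 6.0) * sig
    e = np.zeros_like(r)

    core = r < r0
    if np.any(core):
        g = 1.0 - (r[core] / r0) ** 2
        e[core] += eps * g * g

    depth = params.well_depth[ci, cj]
    if depth > 0.0:
        rc = r0 + params.well_width[ci, cj]
        flat = r <= r0
        e[flat] += -depth
        tailr = (r > r0) & (r < rc)
        if np.any(tailr):
            u = (r[tailr] ** 2 - r0**2) / (rc**2 - r0**2)
            e[tailr] += -depth * (1.0 - u**2) ** 2
    return float(e[0]) if scalar else e


def lipid_pair_force(site_class_i, site_class_j, distance, params: LipidParams):
    """Scalar pair force -dV/dr (kcal/mol/nm); positive = repulsive."""
    ci, cj = _as_class(site_class_i), _as_class(site_class_j)
    r = _check_distance(distance)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)

    sig = params.sigma[ci, cj]
    eps = params.eps_rep[ci, cj]
    r0 = 2.0 ** (1.0 / 6.0) * sig
    f = np.zeros_like(r)

    core = r < r0
    if np.any(core):
        # dV/dr = eps * 2 g * (-2 r / r0^2), g = 1 - (r/r0)^2
        g = 1.0 - (r[core] / r0) ** 2
        f[core] += 4.0 * eps * g * r[core] / r0**2

    depth = params.well_depth[ci, cj]
    if depth > 0.0:
        rc = r0 + params.well_width[ci, cj]
        tailr = (r > r0) & (r < rc)
        if np.any(tailr):
            denom = rc**2 - r0**2
            u = (r[tailr] ** 2 - r0**2) / denom
            # dV/dr = -depth * 2(1-u^2)(-2u) * du/dr, du/dr = 2r/denom
            dVdr = depth * 4.0 * u * (1.0 - u**2) * 2.0 * r[tailr] / denom
            f[tailr] += -dVdr
    return float(f[0]) if scalar else f


def protein_lipid_energy(distance, pot: ProteinLipidPotential, shifted: bool = True):
    """12-6 LJ energy between a scaffold site and a lipid head site.

    With ``shifted=True`` (the simulation form) the energy is shifted to
    zero at the cutoff and vanishes beyond it; ``shifted=False`` returns
    the bare 4*eps*[(sigma/r)^12 - (sigma/r)^6].
    """
    r = _check_distance(distance)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    sr6 = (pot.sigma / r) ** 6
    e = 4.0 * pot.epsilon * (sr6 * sr6 - sr6)
    if shifted:
        e = np.where(r < pot.cutoff, e - pot.shift, 0.0)
    return float(e[0]) if scalar else e


def protein_lipid_force(distance, pot: ProteinLipidPotential):
    """Scalar force -dV/dr of the truncated-shifted protein-head LJ."""
    r = _check_distance(distance)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    sr6 = (pot.sigma / r) ** 6
    f = np.where(r < pot.cutoff, 24.0 * pot.epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    return float(f[0]) if scalar else f


# ----------------------------------------------------------------------
# flattened tables consumed by the numba kernels
# ----------------------------------------------------------------------

def head_eps_scale(params: LipidParams, cls, species) -> np.ndarray:
    """Per-site multiplier on head repulsion strength (species hook).

    The pair kernel multiplies the two sites' scales, so a lipid species
    with scale s has head-head repulsion scaled by s^2 against itself.
    Non-head sites carry 1.0.
    """
    out = np.ones(len(cls))
    heads = np.asarray(cls) == HEAD
    sp = np.asarray(species)
    out[heads & (sp == 1)] = np.sqrt(params.dops_head_scale)
    out[heads & (sp == 0)] = np.sqrt(params.dopc_head_scale)
    return out

def pair_tables(params: LipidParams, pot: ProteinLipidPotential) -> dict:
    """Pack the force field into flat arrays/scalars for the kernels.

    ``hp_*`` entries are the single hydrophobic (body/tail) parameter set
    used by the dominant pair loop; the 3x3 tables cover head-involved
    (repulsion-only) pairs.
    """
    sig2 = params.sigma**2
    r0sq = (2.0 ** (1.0 / 3.0)) * sig2          # (2^(1/6) sigma)^2
    rc = params.cutoff()
    return {
        "sigma2": sig2,
        "eps_rep": params.eps_rep.copy(),
        "depth": params.well_depth.copy(),
        "rcsq": rc**2,
        "hp_r0sq": float(r0sq[BODY, BODY]),
        "hp_depth": float(params.well_depth[BODY, BODY]),
        "hp_rcsq": float(rc[BODY, BODY] ** 2),
        "pl_sigma2": pot.sigma**2,
        "pl_eps": pot.epsilon,
        "pl_rcsq": pot.cutoff**2,
        "pl_shift": pot.shift,
        "max_cutoff": max(params.max_cutoff, pot.cutoff),
    }
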