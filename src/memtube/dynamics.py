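"""Equilibration and production NVT dynamics with frozen scaffold sites.

Integration is velocity Verlet with a Nose-Hoover chain (length 3)
thermostat acting on the lipid sites only; protein scaffold sites are
frozen (never integrated, excluded from the thermostat's degrees of
freedom and from kinetic-temperature reporting).  The equilibration
stage ramps the thermostat target linearly (10 K -> 310 K by default)
starting from Maxwell-Boltzmann velocities at the ramp start.

Time is expressed in the CG unit tau; the integrator step is 1 tau by
default and the trajectory is dumped every ``dump_interval`` tau.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .builder import SimulationSystem
from .cg_model import (
    KB,
    PROTEIN,
    TAU,
    LipidParams,
    ProteinLipidPotential,
    head_eps_scale,
    pair_tables,
)


class SimulationDiverged(RuntimeError):
    """Raised when a site velocity exceeds the divergence guard."""


@dataclass
class RunProtocol:
    """Step counts, thermostat settings and output cadence for one run.

    Defaults are the full-scale protocol (1e6 equilibration steps ramping
    10 K -> 310 K, 1e7 production steps at 310 K, damping 100 tau, dump
    every 10,000 tau).  Desk-scale presets shrink the counts; see
    :mod:`memtube.presets`.
    """

    timestep: float = 1.0            # tau
    equilibration_steps: int = 1_000_000
    ramp_start: float = 10.0         # K
    ramp_end: float = 310.0          # K
    production_steps: int = 10_000_000
    thermostat_target: float = 310.0  # K
    damping: float = 100.0           # tau
    dump_interval: int = 10_000      # tau
    seed: int = 0
    replica: int = 0
    neighbor_skin: float = 0.3       # nm
    guard_vmax: float = 60.0         # divergence guard on |v|
    limit_displacement: float = 0.04  # nm/step cap during equilibration
    log_interval: int = 1_000        # steps between temperature/energy log lines
    use_thermostat: bool = True

    def __post_init__(self):
        if self.equilibration_steps < 0 or self.production_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.ramp_start >= self.ramp_end:
            raise ValueError("ramp start must be below ramp end")
        if self.timestep <= 0 or self.damping <= 0 or self.dump_interval <= 0:
            raise ValueError("timestep, damping and dump interval must be > 0")
        if self.production_steps % self.dump_interval != 0:
            raise ValueError("dump interval must divide production steps")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Trajectory:
    """Ordered snapshots of one production run plus provenance.

    ``times`` are in tau and strictly increasing; every snapshot shares
    the site count and identity arrays of the source system.  The full
    final state (double-precision positions and velocities, thermostat
    state) is kept so runs can be continued in chunks.
    """

    times: np.ndarray                # (F,) tau
    positions: np.ndarray            # (F, N, 3) float32
    box: np.ndarray
    cls: np.ndarray
    lipid_id: np.ndarray
    species: np.ndarray
    leaflet: np.ndarray              # leaflet labels at t0
    meta: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)
    final_state: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.positions.shape[0] != len(self.times):
            raise ValueError("one snapshot per timestamp")

    def frame_system(self, frame: int = -1) -> SimulationSystem:
        """Reconstruct a SimulationSystem from a stored frame (positions in
        float32; for exact continuation use ``final_state``)."""
        return SimulationSystem(
            box=self.box.copy(),
            pos=self.positions[frame].astype(float),
            vel=np.zeros((self.n_sites, 3)),
            cls=self.cls.copy(),
            lipid_id=self.lipid_id.copy(),
            species=self.species.copy(),
            leaflet=self.leaflet.copy(),
            meta=dict(self.meta.get("system_meta", {})),
        )


# ----------------------------------------------------------------------


def _bond_arrays(system: SimulationSystem, params: LipidParams):
    """Harmonic bond table: head-body, body-tail, plus the 1-3 head-tail
    straightening spring, for every lipid."""
    lipid_sites = np.flatnonzero(system.cls != PROTEIN)
    order = np.lexsort((system.cls[lipid_sites], system.lipid_id[lipid_sites]))
    sites = lipid_sites[order].reshape(-1, 3)  # columns: head, body, tail
    h, b, t = sites[:, 0], sites[:, 1], sites[:, 2]
    bi = np.concatenate([h, b, h]).astype(np.int32)
    bj = np.concatenate([b, t, t]).astype(np.int32)
    n = len(h)
    bk = np.concatenate(
        [np.full(2 * n, params.bond_k), np.full(n, params.straight_k)]
    )
    br = np.concatenate(
        [np.full(2 * n, params.bond_length), np.full(n, 2.0 * params.bond_length)]
    )
    return bi, bj, bk, br


class _Engine:
    """Shared setup for equilibrate/run_nvt: tables, bonds, state arrays."""

    def __init__(
        self,
        system: SimulationSystem,
        protocol: RunProtocol,
        params: LipidParams | None = None,
        protein_potential: ProteinLipidPotential | None = None,
    ):
        self.params = params or LipidParams()
        self.pot = protein_potential or ProteinLipidPotential()
        self.protocol = protocol
        self.system = system
        self.tables = pair_tables(self.params, self.pot)

        # frozen sites must come after all lipid sites for the kernel
        frozen = system.cls == PROTEIN
        n_free = system.n_free
        if np.any(frozen[:n_free]):
            raise ValueError("frozen protein sites must follow all lipid sites")

        self.n_free = n_free
        self.pos = system.pos.astype(np.float64).copy()
        self.vel = system.vel.astype(np.float64).copy()
        self.forces = np.zeros_like(self.pos)
        self.box = system.box.astype(np.float64)
        self.cls = system.cls.astype(np.int8)
        self.lipid_id = system.lipid_id.astype(np.int32)
        self.eps_scale = head_eps_scale(self.params, self.cls, system.species)
        self.vxi = np.zeros(3)

        skin = protocol.neighbor_skin
        rc = self.params.cutoff()
        self.rl2_lipid = (rc + skin) ** 2
        self.rl2_pl = (self.pot.cutoff + skin) ** 2
        self.bonds = _bond_arrays(system, self.params)

        self.dt = protocol.timestep * TAU
        self.t_damp = protocol.damping * TAU

    def seed_velocities(self, temperature: float, seed: int) -> None:
        rng = np.random.default_rng(seed)
        v = rng.normal(0.0, np.sqrt(KB * max(temperature, 1e-6)), (self.n_free, 3))
        v -= v.mean(axis=0)
        self.vel[: self.n_free] = v
        self.vel[self.n_free:] = 0.0

    def kinetic_temperature(self) -> float:
        v = self.vel[: self.n_free]
        return float(np.sum(v * v) / (3.0 * self.n_free * KB))

    def run_steps(self, nsteps: int, t0: float, t1: float, max_move: float = 0.0):
        p = self.protocol
        nlog = nsteps // max(p.log_interval, 1)
        log_temp = np.zeros(max(nlog, 1))
        log_epot = np.zeros(max(nlog, 1))
        status = _kernels.md_chunk(
            self.pos, self.vel, self.forces, self.n_free,
            self.cls, self.lipid_id, self.eps_scale, self.box,
            nsteps, self.dt, t0, t1, KB, self.t_damp,
            p.use_thermostat, self.vxi,
            self.tables["sigma2"], self.tables["eps_rep"],
            self.tables["depth"], self.tables["rcsq"],
            self.tables["hp_r0sq"], self.tables["hp_depth"], self.tables["hp_rcsq"],
            self.tables["pl_sigma2"], self.tables["pl_eps"],
            self.tables["pl_rcsq"], self.tables["pl_shift"],
            self.rl2_lipid, self.rl2_pl, p.neighbor_skin,
            *self.bonds,
            p.guard_vmax, p.log_interval, log_temp, log_epot, max_move,
        )
        if status == _kernels.DIVERGED:
            raise SimulationDiverged(
                f"site velocity exceeded {p.guard_vmax} (kinetic T "
                f"{self.kinetic_temperature():.1f} K); last state retained"
            )
        return log_temp[:nlog], log_epot[:nlog]

    def as_system(self) -> SimulationSystem:
        out = self.system.copy()
        out.pos = self.pos.copy()
        out.vel = self.vel.copy()
        return out


def equilibrate(
    system: SimulationSystem,
    protocol: RunProtocol,
    params: LipidParams | None = None,
    protein_potential: ProteinLipidPotential | None = None,
) -> SimulationSystem:
    """Temperature-ramp equilibration; returns the equilibrated system.

    Velocities are drawn at the ramp-start temperature under the protocol
    seed, then the thermostat target ramps linearly to ``ramp_end`` over
    ``equilibration_steps``.  With zero steps the system is returned
    unchanged.  Frozen sites do not move.
    """
    if protocol.equilibration_steps == 0:
        return system.copy()
    eng = _Engine(system, protocol, params, protein_potential)
    eng.seed_velocities(protocol.ramp_start, protocol.seed + 7919 * protocol.replica)
    eng.run_steps(
        protocol.equilibration_steps,
        protocol.ramp_start,
        protocol.ramp_end,
        max_move=protocol.limit_displacement,
    )
    out = eng.as_system()
    out.meta["equilibrated"] = True
    out.meta["kinetic_temperature"] = eng.kinetic_temperature()
    return out


def run_nvt(
    system: SimulationSystem,
    protocol: RunProtocol,
    params: LipidParams | None = None,
    protein_potential: ProteinLipidPotential | None = None,
    stop_condition=None,
) -> Trajectory:
    """Production NVT run; returns a Trajectory dumped every
    ``dump_interval`` tau.

    If ``stop_condition(positions, system) -> bool`` is given it is
    evaluated at every dump and the run ends early once it returns True
    (used e.g. to stop after tube scission); the trajectory then holds
    fewer snapshots than production_steps / dump_interval.
    """
    eng = _Engine(system, protocol, params, protein_potential)
    if not np.any(system.vel[: eng.n_free]):
        warnings.warn("run_nvt started from zero velocities; seeding at the "
                      "thermostat target", stacklevel=2)
        eng.seed_velocities(protocol.thermostat_target,
                            protocol.seed + 7919 * protocol.replica)

    steps_per_dump = int(round(protocol.dump_interval / protocol.timestep))
    n_dumps = protocol.production_steps // steps_per_dump
    T = protocol.thermostat_target

    times = []
    frames = []
    log_t, log_e = [], []
    stopped = False
    for d in range(n_dumps):
        lt, le = eng.run_steps(steps_per_dump, T, T)
        log_t.append(lt)
        log_e.append(le)
        times.append((d + 1) * protocol.dump_interval)
        frames.append(eng.pos.astype(np.float32).copy())
        if stop_condition is not None and stop_condition(eng.pos, system):
            stopped = True
            break

    traj = Trajectory(
        times=np.asarray(times, dtype=float),
        positions=np.asarray(frames),
        box=eng.box.copy(),
        cls=eng.cls.copy(),
        lipid_id=eng.lipid_id.copy(),
        species=system.species.copy(),
        leaflet=system.leaflet.copy(),
        meta={
            "config_hash": protocol.config_hash(),
            "seed": protocol.seed,
            "replica": protocol.replica,
            "stopped_early": stopped,
            "system_meta": dict(system.meta),
            "mean_temperature": (
                float(np.mean(np.concatenate(log_t)))
                if log_t and sum(len(a) for a in log_t) > 0
                else np.nan
            ),
        },
        log={
            "temperature": np.concatenate(log_t) if log_t else np.zeros(0),
            "potential_energy": np.concatenate(log_e) if log_e else np.zeros(0),
        },
        final_state={
            "pos": eng.pos.copy(),
            "vel": eng.vel.copy(),
            "vxi": eng.vxi.copy(),
        },
    )
    traj.validate()
    return traj


def replicate(
    config: dict,
    n_replicas: int,
    stop_condition=None,
) -> list[Trajectory]:
    """Run ``n_replicas`` independent replicas of one system.

    ``config`` holds a builder section (passed to
    :func:`memtube.presets.build_from_config`) and a ``protocol`` section.
    Replicas share all parameters and differ only through the replica
    index, which scrambles initial lipid placement, species assignment
    and initial velocities.
    """
    from .presets import build_from_config

    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    out = []
    for rep in range(n_replicas):
        cfg = json.loads(json.dumps(config))  # deep copy
        cfg.setdefault("build", {})["seed"] = int(cfg.get("build", {}).get("seed", 0)) + 101 * rep
        proto_kwargs = dict(cfg.get("protocol", {}))
        proto_kwargs["replica"] = rep
        protocol = RunProtocol(**proto_kwargs)
        params = LipidParams(**cfg.get("lipid_params", {})) if cfg.get("lipid_params") else None
        pot = (
            ProteinLipidPotential(**cfg["protein_potential"])
            if cfg.get("protein_potential")
            else None
        )
        system = build_from_config(cfg["build"], params=params)
        system = equilibrate(system, protocol, params, pot)
        out.append(run_nvt(system, protocol, params, pot, stop_condition=stop_condition))
    return out
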