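"""Desk-scale simulation experiments: bare-tube stability/fission scans
and scaffolded-tube runs.

These drivers bundle the desk-scale study conditions (tube length,
build tension, run protocol, scaffold geometry) so the same experiment
definition serves the test suite, the acceptance script and interactive
use.  Bare-tube scans build every tube with the same protocol and stop a
run early once scission is detected.

Desk conditions
---------------
Tubes are 30 nm long and built at an area per lipid above the model's
relaxed value, i.e. under membrane tension.  The tension plays the role
of the long production runs of the full-scale protocol: scission of
sub-critical tubes is a stochastic, thermally activated event, and desk
step counts only sample it at an accelerated rate.  All radii in a scan
share the same tension, so the radius ordering of stability is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import SimulationSystem, build_scaffold, build_tube, place_scaffold
from .cg_model import LipidParams, ProteinLipidPotential
from .dynamics import RunProtocol, Trajectory, equilibrate, run_nvt
from .traj_analysis import SimFissionRecord, detect_scission, frame_gaps

# desk-scale study conditions
DESK_TUBE_LENGTH = 30.0          # nm
DESK_APL_BUILD = 0.80            # nm^2; above the relaxed value -> tension
DESK_EQUIL_STEPS = 5_000
DESK_PRODUCTION_STEPS = 12_000
DESK_DUMP_INTERVAL = 1_000       # tau
DESK_SCAFFOLD_RING_GAP = 1.0     # nm above the tube outer radius
DESK_SCAFFOLD_CUTOFF = 1.0       # nm protein-head LJ cutoff (5 sigma)


def desk_protocol(
    seed: int,
    replica: int = 0,
    production_steps: int = DESK_PRODUCTION_STEPS,
    equilibration_steps: int = DESK_EQUIL_STEPS,
    dump_interval: int = DESK_DUMP_INTERVAL,
) -> RunProtocol:
    return RunProtocol(
        equilibration_steps=equilibration_steps,
        production_steps=production_steps,
        dump_interval=dump_interval,
        seed=seed,
        replica=replica,
        neighbor_skin=0.4,
    )


def _stop_on_gap(system: SimulationSystem):
    def stop(pos, _sys):
        return len(frame_gaps(pos, system.cls, system.box)) > 0

    return stop


@dataclass
class BareTubeRun:
    lumen_radius: float              # nm, as built
    replica: int
    record: SimFissionRecord
    trajectory: Trajectory | None = None


def run_bare_tube(
    lumen_radius: float,
    seed: int,
    replica: int = 0,
    params: LipidParams | None = None,
    production_steps: int = DESK_PRODUCTION_STEPS,
    equilibration_steps: int = DESK_EQUIL_STEPS,
    dump_interval: int = DESK_DUMP_INTERVAL,
    length: float = DESK_TUBE_LENGTH,
    apl: float = DESK_APL_BUILD,
    keep_trajectory: bool = False,
) -> BareTubeRun:
    """Build, equilibrate and run one bare desk tube; stop at scission."""
    params = params or LipidParams()
    system = build_tube(
        length=length,
        lumen_diameter=2.0 * lumen_radius,
        seed=seed + 101 * replica,
        params=params,
        apl=apl,
        box_margin=4.5,
    )
    proto = desk_protocol(seed, replica, production_steps, equilibration_steps, dump_interval)
    system = equilibrate(system, proto, params)
    traj = run_nvt(system, proto, params, stop_condition=_stop_on_gap(system))
    rec = detect_scission(traj)
    return BareTubeRun(
        lumen_radius=lumen_radius,
        replica=replica,
        record=rec,
        trajectory=traj if keep_trajectory else None,
    )


def scan_bare_tubes(
    lumen_radii,
    n_replicas: int = 3,
    seed: int = 0,
    params: LipidParams | None = None,
    production_steps: int = DESK_PRODUCTION_STEPS,
    equilibration_steps: int = DESK_EQUIL_STEPS,
    dump_interval: int = DESK_DUMP_INTERVAL,
    verbose: bool = False,
) -> dict:
    """Replicated stability/fission scan over initial lumen radii (nm)."""
    out: dict[float, list[BareTubeRun]] = {}
    for i, r in enumerate(lumen_radii):
        runs = []
        for rep in range(n_replicas):
            run = run_bare_tube(
                r, seed=seed + 13 * i, replica=rep, params=params,
                production_steps=production_steps,
                equilibration_steps=equilibration_steps,
                dump_interval=dump_interval,
            )
            runs.append(run)
            if verbose:
                rec = run.record
                print(
                    f"  lumen r={r} rep={rep}: fission={rec.fission}"
                    + (f" t={rec.time:.0f} pre_r={rec.pre_scission_radius}" if rec.fission else ""),
                    flush=True,
                )
        out[float(r)] = runs
    return out


def largest_fissioning_radius(scan: dict) -> float:
    """Largest initial lumen radius whose replicas fission in the
    majority; 0.0 if no radius does."""
    best = 0.0
    for r, runs in scan.items():
        k = sum(1 for run in runs if run.record.fission)
        if 2 * k > len(runs):
            best = max(best, float(r))
    return best


# ----------------------------------------------------------------------
# scaffolded runs
# ----------------------------------------------------------------------

def desk_protein_potential() -> ProteinLipidPotential:
    return ProteinLipidPotential(cutoff=DESK_SCAFFOLD_CUTOFF)


def run_scaffolded_tube(
    scaffold_fraction: float,
    seed: int,
    lumen_radius: float = 2.75,
    replica: int = 0,
    params: LipidParams | None = None,
    production_steps: int = DESK_PRODUCTION_STEPS,
    length: float = DESK_TUBE_LENGTH,
    apl: float = DESK_APL_BUILD,
) -> Trajectory:
    """Tube with a frozen ring scaffold covering ``scaffold_fraction`` of
    its length, run with the desk protocol (early stop at scission).

    The scaffold ring radius sits ``DESK_SCAFFOLD_RING_GAP`` above the
    tube's outer radius, scaled-down counterpart of the full-scale
    25 nm ring over a 20 nm tube.
    """
    params = params or LipidParams()
    pot = desk_protein_potential()
    system = build_tube(
        length=length,
        lumen_diameter=2.0 * lumen_radius,
        seed=seed + 101 * replica,
        params=params,
        apl=apl,
        box_margin=5.0 + DESK_SCAFFOLD_RING_GAP,
    )
    scaffold = build_scaffold(
        scaffold_length=scaffold_fraction * length,
        ring_diameter=2.0 * (system.meta["outer_radius"] + DESK_SCAFFOLD_RING_GAP),
        axial_center=0.5 * length,
    )
    system = place_scaffold(system, scaffold)
    proto = desk_protocol(seed, replica, production_steps)
    system = equilibrate(system, proto, params, pot)
    return run_nvt(system, proto, params, pot, stop_condition=_stop_on_gap(system))
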