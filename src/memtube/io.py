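"""Snapshot and trajectory I/O: extended XYZ, LAMMPS-dump-style text, HDF5.

HDF5 layout (columnar, one group per object):
  /system: box, pos, vel, cls, lipid_id, species, leaflet (+ meta as JSON attr)
  /trajectory: times, positions, box, cls, lipid_id, species, leaflet,
               log/*, final_state/* (+ meta as JSON attr)
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .builder import SimulationSystem
from .cg_model import CLASS_NAMES
from .dynamics import Trajectory

_SPECIES = {0: "DOPC", 1: "DOPS", -1: "PROT"}


def _xyz_lines(pos, cls, species, box, comment):
    lines = [str(len(pos))]
    lines.append(
        f'Lattice="{box[0]} 0 0 0 {box[1]} 0 0 0 {box[2]}" '
        f"Properties=species:S:1:pos:R:3:site_class:S:1 {comment}"
    )
    for p, c, s in zip(pos, cls, species):
        lines.append(
            f"{_SPECIES[int(s)]} {p[0]:.5f} {p[1]:.5f} {p[2]:.5f} {CLASS_NAMES[int(c)]}"
        )
    return lines


def write_xyz(obj, path, frame: int | None = None) -> None:
    """Write a system snapshot, or all (or one) trajectory frames, as
    extended XYZ."""
    if isinstance(obj, SimulationSystem):
        lines = _xyz_lines(obj.pos, obj.cls, obj.species, obj.box, "t=0")
    else:
        frames = range(obj.n_frames) if frame is None else [frame]
        lines = []
        for f in frames:
            lines += _xyz_lines(
                obj.positions[f], obj.cls, obj.species, obj.box, f"t={obj.times[f]:g}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_lammps_dump(traj: Trajectory, path) -> None:
    """LAMMPS-dump-style text trajectory for external visualization."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n%d\n" % int(traj.times[f]))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % traj.n_sites)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {traj.box[d]:.6f}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            pos = traj.positions[f]
            for i in range(traj.n_sites):
                fh.write(
                    f"{i + 1} {int(traj.cls[i]) + 1} "
                    f"{pos[i, 0]:.4f} {pos[i, 1]:.4f} {pos[i, 2]:.4f}\n"
                )


def save_system(system: SimulationSystem, path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("system")
        for name in ("box", "pos", "vel", "cls", "lipid_id", "species", "leaflet"):
            g.create_dataset(name, data=getattr(system, name))
        g.attrs["meta"] = json.dumps(system.meta, default=str)


def load_system(path) -> SimulationSystem:
    with h5py.File(path, "r") as fh:
        g = fh["system"]
        return SimulationSystem(
            box=g["box"][()],
            pos=g["pos"][()],
            vel=g["vel"][()],
            cls=g["cls"][()],
            lipid_id=g["lipid_id"][()],
            species=g["species"][()],
            leaflet=g["leaflet"][()],
            meta=json.loads(g.attrs["meta"]),
        )


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("trajectory")
        for name in ("times", "positions", "box", "cls", "lipid_id", "species", "leaflet"):
            g.create_dataset(name, data=getattr(traj, name))
        g.attrs["meta"] = json.dumps(traj.meta, default=str)
        lg = g.create_group("log")
        for k, v in traj.log.items():
            lg.create_dataset(k, data=v)
        if traj.final_state is not None:
            sg = g.create_group("final_state")
            for k, v in traj.final_state.items():
                sg.create_dataset(k, data=v)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        g = fh["trajectory"]
        final = None
        if "final_state" in g:
            final = {k: g["final_state"][k][()] for k in g["final_state"]}
        return Trajectory(
            times=g["times"][()],
            positions=g["positions"][()],
            box=g["box"][()],
            cls=g["cls"][()],
            lipid_id=g["lipid_id"][()],
            species=g["species"][()],
            leaflet=g["leaflet"][()],
            meta=json.loads(g.attrs["meta"]),
            log={k: g["log"][k][()] for k in g["log"]},
            final_state=final,
        )
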