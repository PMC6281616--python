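"""Named system presets and config-driven building.

Two presets ship with the package:

``paper_full``
    The full-scale reference system: 100 nm tube, outer diameter 20 nm,
    lumen diameter 11 nm, 14,500 lipids at 40:60 DOPS:DOPC in a
    100 x 50 x 50 nm box; 1e6-step temperature ramp and 1e7-step
    production with dumps every 10,000 tau.  Scaffolds are rings of
    diameter 25 nm (35 sites, 0.25 nm apart axially).

``desk_small``
    A scaled-down tube (30 nm long) with proportionally fewer lipids and
    short runs, for desktop-scale experiments and the test suite.  The
    scaffold ring radius tracks the tube outer radius at a fixed radial
    gap, and the protein-head attraction uses a wider cutoff so that the
    attraction band stays within reach of thermal undulations of the
    scaled-down tube.

A config dict (or YAML file) holds sections ``build``, ``protocol``,
``lipid_params``, ``protein_potential``; see ``configs/*.yaml``.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

from .builder import SimulationSystem, build_patch, build_scaffold, build_tube, place_scaffold
from .cg_model import LipidParams, ProteinLipidPotential


def load_config(path_or_name) -> dict:
    """Load a config: a shipped preset name ('paper_full', 'desk_small')
    or a path to a YAML file."""
    name = str(path_or_name)
    if name in ("paper_full", "desk_small"):
        text = resources.files("memtube").joinpath(f"configs/{name}.yaml").read_text()
        return yaml.safe_load(text)
    with open(name) as fh:
        return yaml.safe_load(fh)


def build_from_config(build_cfg: dict, params: LipidParams | None = None) -> SimulationSystem:
    """Build a system from a config ``build`` section.

    Keys: ``kind`` ('tube' or 'patch'), builder arguments, and an
    optional ``scaffold`` sub-section.  A scaffold may give either
    ``ring_diameter`` directly or ``ring_gap`` (radial clearance added to
    the tube's outer radius); ``scaffold_length`` may instead be given as
    ``length_fraction`` of the tube length.
    """
    cfg = copy.deepcopy(build_cfg)
    kind = cfg.pop("kind", "tube")
    scaffold_cfg = cfg.pop("scaffold", None)
    params = params or LipidParams()

    if kind == "patch":
        return build_patch(params=params, **cfg)
    if kind != "tube":
        raise ValueError(f"unknown build kind: {kind}")

    system = build_tube(params=params, **cfg)
    if scaffold_cfg:
        s = dict(scaffold_cfg)
        length = system.meta["length"]
        if "length_fraction" in s:
            s["scaffold_length"] = float(s.pop("length_fraction")) * length
        if "ring_gap" in s:
            s["ring_diameter"] = 2.0 * (system.meta["outer_radius"] + float(s.pop("ring_gap")))
        s.setdefault("axial_center", 0.5 * length)
        scaffold = build_scaffold(**s)
        system = place_scaffold(system, scaffold)
    return system


def protein_potential_from_config(cfg: dict) -> ProteinLipidPotential:
    return ProteinLipidPotential(**cfg.get("protein_potential", {}))


def lipid_params_from_config(cfg: dict) -> LipidParams:
    return LipidParams(**cfg.get("lipid_params", {}))
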