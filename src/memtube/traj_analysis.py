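"""Simulation observables: lumen-radius profiles, thinning kinetics,
scission detection, and interleaflet mixing.

All radial measurements are taken relative to the instantaneous tube
axis, estimated per snapshot as the line parallel to x through the lipid
center of mass in (y, z).  The lumen radius of an axial bin is the mean
radial distance of inner-leaflet head sites in that bin.

Scission is detected from axial connectivity of the hydrophobic (body +
tail) sites: the tube is intact at axial position x if at least one
contact pair of hydrophobic sites spans x.  A frame is "severed" when an
axial window wider than ``min_gap`` is spanned by no contact pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import INNER, OUTER
from .cg_model import BODY, HEAD, PROTEIN, TAIL
from .dynamics import Trajectory


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def tube_axis_center(pos: np.ndarray, cls: np.ndarray) -> np.ndarray:
    """(y, z) of the instantaneous tube axis: lipid center of mass.

    Assumes the tube does not cross the y/z box boundaries (builders
    center it with a margin).
    """
    lipid = cls != PROTEIN
    return pos[lipid, 1:].mean(axis=0)


def radial_distance(pos: np.ndarray, center: np.ndarray) -> np.ndarray:
    d = pos[:, 1:] - center[None, :]
    return np.sqrt(np.sum(d * d, axis=1))


def assign_leaflets(
    pos: np.ndarray,
    cls: np.ndarray,
    lipid_id: np.ndarray,
    prior: np.ndarray,
    ambiguous: float = 0.05,
) -> np.ndarray:
    """Per-lipid leaflet assignment from head-minus-body radial component.

    A head farther from the axis than its body site marks an outer-leaflet
    lipid.  Lipids whose |radial component| is below ``ambiguous`` (nm)
    keep their prior label.  Returns per-site labels.
    """
    center = tube_axis_center(pos, cls)
    r = radial_distance(pos, center)
    lipid = cls != PROTEIN
    order = np.lexsort((cls[lipid], lipid_id[lipid]))
    sites = np.flatnonzero(lipid)[order].reshape(-1, 3)  # head, body, tail
    comp = r[sites[:, 0]] - r[sites[:, 1]]
    out = prior.copy()
    lab = np.where(comp > 0, OUTER, INNER).astype(np.int8)
    keep = np.abs(comp) < ambiguous
    prior_per_lipid = prior[sites[:, 0]]
    lab[keep] = prior_per_lipid[keep]
    for c in range(3):
        out[sites[:, c]] = lab
    return out


# ----------------------------------------------------------------------
# lumen radius
# ----------------------------------------------------------------------

@dataclass
class LumenProfile:
    """Axially binned lumen radius averaged over a snapshot window."""

    bin_centers: np.ndarray          # nm, strictly increasing
    mean: np.ndarray                 # nm
    variance: np.ndarray             # nm^2
    n_snapshots: int
    scaffold_boundaries: tuple | None = None
    empty: np.ndarray = None         # bins with no site in any snapshot

    def __post_init__(self):
        if self.empty is None:
            self.empty = np.isnan(self.mean)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_nm": self.bin_centers,
                "lumen_radius_nm": self.mean,
                "variance_nm2": self.variance,
                "empty": self.empty,
            }
        )

    def plot(self, path=None, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.plot(self.bin_centers, self.mean, color="C0")
        ax.fill_between(
            self.bin_centers,
            self.mean - np.sqrt(np.maximum(self.variance, 0.0)),
            self.mean + np.sqrt(np.maximum(self.variance, 0.0)),
            alpha=0.3,
            color="C0",
        )
        if self.scaffold_boundaries is not None:
            for b in self.scaffold_boundaries:
                ax.axvline(b, color="gray", lw=1)
        ax.set_xlabel("position along tube (nm)")
        ax.set_ylabel("lumen radius (nm)")
        if path:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def _frame_profile(
    pos, cls, lipid_id, leaflet, box, n_bins, prior_leaflet=None
) -> np.ndarray:
    """Single-snapshot per-bin lumen radius (NaN for empty bins)."""
    labels = assign_leaflets(pos, cls, lipid_id,
                             leaflet if prior_leaflet is None else prior_leaflet)
    center = tube_axis_center(pos, cls)
    sel = (cls == HEAD) & (labels == INNER)
    x = pos[sel, 0] % box[0]
    r = radial_distance(pos[sel], center)
    edges = np.linspace(0.0, box[0], n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def default_n_bins(box_x: float) -> int:
    """1 nm bins (100 bins at full scale), scaled with tube length."""
    return max(10, int(round(box_x)))


def lumen_radius_profile(
    traj: Trajectory,
    n_bins: int | None = None,
    snapshot_window: slice | None = None,
) -> LumenProfile:
    """Mean/variance lumen-radius profile over a snapshot window.

    The default window is the last 20 dumped snapshots.  Bins with no
    inner-leaflet head site in any window snapshot are flagged ``empty``
    and carry NaN.
    """
    if n_bins is None:
        n_bins = default_n_bins(traj.box[0])
    if snapshot_window is None:
        snapshot_window = slice(max(0, traj.n_frames - 20), traj.n_frames)
    frames = range(*snapshot_window.indices(traj.n_frames))
    per = np.array(
        [
            _frame_profile(
                traj.positions[f].astype(float),
                traj.cls,
                traj.lipid_id,
                traj.leaflet,
                traj.box,
                n_bins,
            )
            for f in frames
        ]
    )
    if per.size == 0:
        raise ValueError("snapshot window selects no frames")
    edges = np.linspace(0.0, traj.box[0], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per, axis=0)
        var = np.nanvar(per, axis=0)
    return LumenProfile(
        bin_centers=centers,
        mean=mean,
        variance=var,
        n_snapshots=len(per),
        scaffold_boundaries=traj.meta.get("system_meta", {}).get("scaffold_boundaries"),
    )


# ----------------------------------------------------------------------
# scission detection
# ----------------------------------------------------------------------

@dataclass
class SimFissionRecord:
    """Outcome of scission detection on one trajectory."""

    fission: bool
    time: float | None = None            # tau of first severed snapshot
    position: float | None = None        # nm, center of the gap
    pre_scission_radius: float | None = None  # nm, at that position, last intact frame
    all_positions: list = field(default_factory=list)
    frame: int | None = None


def frame_gaps(
    pos: np.ndarray,
    cls: np.ndarray,
    box: np.ndarray,
    contact_cutoff: float = 1.1,
    min_gap: float = 0.3,
    resolution: float = 0.05,
) -> list[tuple[float, float]]:
    """Axial windows (start, width) spanned by no hydrophobic contact pair.

    The x-interval covered by each contact pair of body/tail sites is
    rasterized onto a fine grid; runs of uncovered cells wider than
    ``min_gap`` are reported.  Periodicity in x is honored.
    """
    L = box[0]
    hydro = (cls == BODY) | (cls == TAIL)
    p = pos[hydro].copy()
    p[:, 0] %= L
    tree = cKDTree(p, boxsize=box)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    n_cells = max(16, int(np.ceil(L / resolution)))
    covered = np.zeros(n_cells, dtype=bool)
    scale = n_cells / L
    xi = p[pairs[:, 0], 0]
    xj = p[pairs[:, 1], 0]
    dx = xj - xi
    dx -= L * np.rint(dx / L)
    lo = np.where(dx >= 0, xi, xj)
    w = np.abs(dx)
    a = np.floor(lo * scale).astype(np.int64)
    bcells = np.floor((lo + w) * scale).astype(np.int64)
    for s, e in zip(a, bcells):
        if e < n_cells:
            covered[s : e + 1] = True
        else:
            covered[s:] = True
            covered[: e - n_cells + 1] = True
    # also cover cells holding any hydrophobic site (a site is lipid body)
    site_cells = np.floor(p[:, 0] * scale).astype(np.int64) % n_cells
    covered[site_cells] = True

    if covered.all():
        return []
    # find uncovered runs on the circle
    gaps = []
    idx = np.flatnonzero(~covered)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    # merge wrap-around run
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n_cells - 1:
        runs[0] = np.concatenate([runs[-1] - n_cells, runs[0]])
        runs = runs[:-1]
    for run in runs:
        width = len(run) / scale
        if width >= min_gap:
            start = (run[0] / scale) % L
            gaps.append((float(start), float(width)))
    return gaps


def detect_scission(
    traj: Trajectory,
    contact_cutoff: float = 1.1,
    min_gap: float = 0.3,
) -> SimFissionRecord:
    """First snapshot at which the tube is severed, with gap position and
    the lumen radius at that position in the last intact snapshot.

    With several simultaneous gaps the earliest frame and then the
    smallest x position is reported; all gap positions are listed.
    """
    n_bins = default_n_bins(traj.box[0])
    for f in range(traj.n_frames):
        pos = traj.positions[f].astype(float)
        gaps = frame_gaps(pos, traj.cls, traj.box, contact_cutoff, min_gap)
        if gaps:
            centers = sorted((g[0] + 0.5 * g[1]) % traj.box[0] for g in gaps)
            position = centers[0]
            pre_r = None
            if f > 0:
                prof = _frame_profile(
                    traj.positions[f - 1].astype(float),
                    traj.cls, traj.lipid_id, traj.leaflet, traj.box, n_bins,
                )
                # the pre-scission radius is the thinnest lumen near the
                # break (the neck); a lumen stripped of inner-leaflet
                # heads (fully collapsed) has radius 0 by definition
                b = min(int(position / traj.box[0] * n_bins), n_bins - 1)
                halfw = max(1, int(np.ceil(2.0 * n_bins / traj.box[0])))
                idx = (np.arange(b - halfw, b + halfw + 1)) % n_bins
                near = prof[idx]
                if np.any(~np.isnan(near)):
                    pre_r = float(np.nanmin(near))
                elif np.any(~np.isnan(prof)):
                    pre_r = float(np.nanmin(prof))
                else:
                    pre_r = 0.0
            return SimFissionRecord(
                fission=True,
                time=float(traj.times[f]),
                position=float(position),
                pre_scission_radius=pre_r,
                all_positions=centers,
                frame=f,
            )
    return SimFissionRecord(fission=False)


# ----------------------------------------------------------------------
# thinning kinetics and mixing
# ----------------------------------------------------------------------

@dataclass
class ThinningSeries:
    """Lumen radius vs time at the tube middle and at the thinnest
    off-scaffold site.  Post-fission snapshots are NaN and flagged."""

    times: np.ndarray
    r_middle: np.ndarray
    r_thinnest: np.ndarray
    thinnest_position: np.ndarray
    fission_frame: int | None = None


def thinning_timeseries(
    traj: Trajectory,
    scaffold_boundaries: tuple | None = None,
    n_bins: int | None = None,
) -> ThinningSeries:
    """Per-snapshot lumen radius at the tube middle and at the site of
    maximum thinning (minimum radius outside the scaffold boundaries)."""
    if n_bins is None:
        n_bins = default_n_bins(traj.box[0])
    if scaffold_boundaries is None:
        scaffold_boundaries = traj.meta.get("system_meta", {}).get("scaffold_boundaries")
    L = traj.box[0]
    centers = (np.arange(n_bins) + 0.5) * L / n_bins
    outside = np.ones(n_bins, dtype=bool)
    if scaffold_boundaries is not None:
        lo, hi = scaffold_boundaries
        outside = (centers < lo) | (centers > hi)
    mid_bin = int(n_bins // 2)

    rec = detect_scission(traj)
    stop = rec.frame if rec.fission else traj.n_frames

    r_mid = np.full(traj.n_frames, np.nan)
    r_thin = np.full(traj.n_frames, np.nan)
    x_thin = np.full(traj.n_frames, np.nan)
    for f in range(stop):
        prof = _frame_profile(
            traj.positions[f].astype(float),
            traj.cls, traj.lipid_id, traj.leaflet, traj.box, n_bins,
        )
        r_mid[f] = prof[mid_bin]
        cand = np.where(outside, prof, np.nan)
        if np.any(~np.isnan(cand)):
            k = int(np.nanargmin(cand))
            r_thin[f] = cand[k]
            x_thin[f] = centers[k]
    return ThinningSeries(
        times=traj.times.copy(),
        r_middle=r_mid,
        r_thinnest=r_thin,
        thinnest_position=x_thin,
        fission_frame=rec.frame if rec.fission else None,
    )


def interleaflet_mixing(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of lipids whose leaflet assignment changed vs the t0
    labels, per snapshot.  Total lipid count is conserved throughout."""
    n_lipids = int(np.sum(traj.cls != PROTEIN)) // 3
    frac = np.empty(traj.n_frames)
    prior = traj.leaflet.copy()
    lipid = traj.cls != PROTEIN
    order = np.lexsort((traj.cls[lipid], traj.lipid_id[lipid]))
    head_sites = np.flatnonzero(lipid)[order].reshape(-1, 3)[:, 0]
    ref = traj.leaflet[head_sites]
    for f in range(traj.n_frames):
        labels = assign_leaflets(
            traj.positions[f].astype(float), traj.cls, traj.lipid_id, prior
        )
        cur = labels[head_sites]
        assert cur.size == n_lipids
        frac[f] = float(np.mean(cur != ref))
        prior = labels
    return traj.times.copy(), frac
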