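"""Fluorescence tube morphometry: intensity-to-radius calibration,
protein/membrane coupling, bulge and fission kinetics, FRAP, and scaffold
growth rates.

The central calibration follows the standard two-slope scheme for
diffraction-limited membrane tubes.  A supported lipid bilayer (SLB) of
known geometry gives the intensity emitted per unit membrane area, k1
(a.u. nm^-2), from integrated densities of ROIs of different sizes.  The
integrated density ID of a tube segment of length l then converts to a
radius through

    r = ID / (k1 * 2 * pi * l)

because a tube of radius r carries membrane area 2*pi*r per unit length.
Radius estimates obtained this way reflect the distance from the lumen
to the center of the lipid bilayer.  A second slope k2 (a.u. nm^-1),
fitted from peak tube intensity against tube radius, converts per-pixel
peak intensities into a per-pixel radius profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class CalibrationError(ValueError):
    """Raised for degenerate or inconsistent calibration inputs."""


@dataclass
class CalibrationConstants:
    """Calibration slopes with fit provenance."""

    k1: float | None = None          # a.u. per nm^2 membrane
    k2: float | None = None          # a.u. per nm radius
    n_rois: int = 0
    residual: float = 0.0            # rms relative residual of the fit


@dataclass
class TubeMovie:
    """Time-stamped intensity frames of one (horizontal) tube.

    ``frames`` has shape (T, H, W); multi-channel data uses one TubeMovie
    per channel with shared times.  ``background`` is an additive offset
    already present in the frames.
    """

    frames: np.ndarray
    pixel_size: float                # nm per pixel
    times: np.ndarray                # s
    channel: str = "membrane"
    background: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class BulgeRecord:
    """One contiguous region whose radius deviates from the local baseline.

    ``radius`` is the extreme radius in the region: above baseline for a
    bulge (R_b), below for a constriction (R_c, ``constriction=True``).
    """

    position: float                  # nm from the tube's left end
    radius: float                    # nm (R_b or R_c)
    baseline: float                  # nm
    onset_time: float | None = None  # s
    constriction: bool = False
    span: tuple = (0.0, 0.0)         # nm extent


@dataclass
class FissionEvent:
    tube_id: int
    onset_time: float                # s, first frame the bulge criterion fired
    scission_time: float             # s
    position: float = np.nan         # nm

    @property
    def fission_time(self) -> float:
        """Interval between bulge onset and scission (s)."""
        return self.scission_time - self.onset_time


@dataclass
class FrapTrace:
    """A single-spot FRAP record: prebleach level, bleach point, recovery."""

    f_prebleach: float
    times: np.ndarray                # s, from the bleach
    recovery: np.ndarray             # fluorescence F_t

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.recovery = np.asarray(self.recovery, dtype=float)
        if self.times.shape != self.recovery.shape:
            raise ValueError("times and recovery must align")

    @property
    def f_bleach(self) -> float:
        return float(self.recovery[0])


@dataclass
class FrapFit:
    mobile_fraction: float
    half_time: float                 # s
    f_inf: float
    residual: float
    model: str = "hyperbolic"


@dataclass
class GrowthRate:
    rate: float                      # nm/s, signed
    intercept: float
    low_confidence: bool = False


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

def _roi_slice(roi):
    r0, c0, h, w = roi
    return slice(r0, r0 + h), slice(c0, c0 + w)


def integrated_density(image, roi) -> float:
    """Sum of pixel intensities over a rectangular ROI (row0, col0, h, w)."""
    sr, sc = _roi_slice(roi)
    return float(np.sum(image[sr, sc]))


def calibrate_k1(slb_image, rois, pixel_size: float) -> CalibrationConstants:
    """Fit k1 (intensity per nm^2) from ROIs on a background-corrected SLB.

    The integrated densities of the ROIs are regressed against their
    areas with the intercept forced to zero.  At least three ROIs of at
    least two distinct sizes are required.
    """
    if len(rois) < 3:
        raise CalibrationError("need at least 3 ROIs")
    areas = np.array([h * w for (_, _, h, w) in rois], dtype=float) * pixel_size**2
    if np.unique(areas).size < 2:
        raise CalibrationError("ROIs must span more than one area")
    ids = np.array([integrated_density(slb_image, r) for r in rois])
    k1 = float(np.dot(areas, ids) / np.dot(areas, areas))
    if k1 <= 0:
        raise CalibrationError(f"non-positive k1 ({k1:.3g}); check background correction")
    resid = float(np.sqrt(np.mean((ids - k1 * areas) ** 2)) / np.mean(ids))
    return CalibrationConstants(k1=k1, n_rois=len(rois), residual=resid)


def radius_from_integrated_density(ID: float, l: float, k1: float) -> float:
    """Tube radius (nm) from the integrated density of a segment of
    length l (nm): r = ID / (k1 * 2 * pi * l)."""
    if l <= 0:
        raise ValueError("segment length must be > 0")
    if k1 <= 0:
        raise ValueError("k1 must be > 0")
    if ID < 0:
        raise ValueError("integrated density must be >= 0")
    return float(ID / (k1 * 2.0 * np.pi * l))


def tube_peak_intensity(tube_image) -> float:
    """Peak intensity of a background-corrected tube image (max over the
    transverse direction of the axial-mean profile maximum)."""
    img = np.asarray(tube_image, dtype=float)
    return float(img.max())


def calibrate_k2(tube_images, radii) -> CalibrationConstants:
    """Fit k2 (peak intensity per nm radius) through the origin from
    tubes of known radii.

    Requires >= 3 tubes; warns if the radius range spans less than
    two-fold (the slope is then poorly constrained).
    """
    radii = np.asarray(radii, dtype=float)
    if len(tube_images) != len(radii):
        raise CalibrationError("one radius per tube image")
    if len(radii) < 2 or np.unique(radii).size < 2:
        raise CalibrationError("need tubes of more than one size")
    if len(radii) < 3:
        raise CalibrationError("need at least 3 tubes")
    if radii.max() < 2.0 * radii.min():
        warnings.warn("tube radii span less than two-fold; k2 poorly constrained",
                      stacklevel=2)
    peaks = np.array([tube_peak_intensity(t) for t in tube_images])
    k2 = float(np.dot(radii, peaks) / np.dot(radii, radii))
    if k2 <= 0:
        raise CalibrationError("non-positive k2")
    resid = float(np.sqrt(np.mean((peaks - k2 * radii) ** 2)) / np.mean(peaks))
    return CalibrationConstants(k2=k2, n_rois=len(radii), residual=resid)


def radius_profile(peak_trace, k2: float, clip_warn: bool = True) -> np.ndarray:
    """Per-pixel tube radius (nm) from a background-corrected peak-intensity
    trace: r = intensity / k2.  Negative corrected intensities are clipped
    to zero (and flagged with a warning)."""
    if k2 <= 0:
        raise ValueError("k2 must be > 0")
    trace = np.asarray(peak_trace, dtype=float)
    r = trace / k2
    if np.any(r < 0):
        if clip_warn:
            warnings.warn(f"{int(np.sum(r < 0))} negative intensities clipped to 0",
                          stacklevel=2)
        r = np.clip(r, 0.0, None)
    return r


# ----------------------------------------------------------------------
# protein-membrane coupling
# ----------------------------------------------------------------------

def protein_membrane_ratio(protein_img, membrane_img, roi) -> float:
    """Ratio of mean protein to mean membrane intensity over one ROI.

    Both channels must be background-corrected and co-registered.
    """
    sr, sc = _roi_slice(roi)
    m = float(np.mean(np.asarray(membrane_img, dtype=float)[sr, sc]))
    p = float(np.mean(np.asarray(protein_img, dtype=float)[sr, sc]))
    if m <= 0:
        raise ValueError("mean membrane intensity must be > 0 in the ROI")
    return p / m


def pearson_protein_membrane(protein_trace, membrane_trace) -> float:
    """Pearson product-moment correlation between protein and membrane
    fluorescence sampled along one tube."""
    p = np.asarray(protein_trace, dtype=float)
    m = np.asarray(membrane_trace, dtype=float)
    if p.shape != m.shape or p.size < 3:
        raise ValueError("need equal-length traces with n >= 3")
    if np.std(p) == 0 or np.std(m) == 0:
        raise ValueError("correlation undefined for zero-variance traces")
    return float(stats.pearsonr(p, m)[0])


# ----------------------------------------------------------------------
# bulge detection and fission kinetics
# ----------------------------------------------------------------------

def rolling_baseline(r: np.ndarray, window: int) -> np.ndarray:
    """Running median with reflected edges — the local tube baseline."""
    from scipy.ndimage import median_filter

    return median_filter(r, size=max(3, window), mode="reflect")


def detect_bulges(
    radius_prof,
    pixel_size: float,
    baseline_window: float = 5000.0,
    threshold_fraction: float = 0.20,
    merge_distance: float = 200.0,
    detect_constrictions: bool = False,
) -> tuple[list[BulgeRecord], float]:
    """Find bulges (or constrictions) on a calibrated radius profile.

    Contiguous runs where the radius exceeds baseline*(1 + threshold)
    (or falls below baseline*(1 - threshold)) are reported; runs closer
    than ``merge_distance`` (nm) are merged.  Returns the records and
    the density per micrometre of tube.
    """
    r = np.asarray(radius_prof, dtype=float)
    win_px = int(round(baseline_window / pixel_size))
    if len(r) < 3 or len(r) * pixel_size < baseline_window:
        raise ValueError("tube shorter than the baseline window")
    base = rolling_baseline(r, win_px)
    if detect_constrictions:
        above = r < base * (1.0 - threshold_fraction)
    else:
        above = r > base * (1.0 + threshold_fraction)

    # runs of True
    idx = np.flatnonzero(above)
    records: list[BulgeRecord] = []
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = [(run[0], run[-1]) for run in np.split(idx, splits + 1)]
        # merge nearby runs
        merged = [runs[0]]
        gap_px = merge_distance / pixel_size
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap_px:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            seg = r[s : e + 1]
            k = int(np.argmin(seg) if detect_constrictions else np.argmax(seg))
            records.append(
                BulgeRecord(
                    position=(s + k) * pixel_size,
                    radius=float(seg[k]),
                    baseline=float(base[s + k]),
                    constriction=detect_constrictions,
                    span=(s * pixel_size, (e + 1) * pixel_size),
                )
            )
    length_um = len(r) * pixel_size / 1000.0
    return records, len(records) / length_um


def fission_kinetics(events, observation_window) -> dict:
    """Cumulative-cuts curve and per-event fission times.

    ``events`` are FissionEvent records whose times must fall inside the
    (t0, t1) observation window; events with scission before onset are
    rejected.  The cumulative curve is right-continuous.
    """
    t0, t1 = observation_window
    accepted = []
    for ev in events:
        if ev.scission_time < ev.onset_time:
            warnings.warn(f"rejected event on tube {ev.tube_id}: scission before onset",
                          stacklevel=2)
            continue
        if not (t0 <= ev.scission_time <= t1):
            warnings.warn(f"rejected event on tube {ev.tube_id}: outside window",
                          stacklevel=2)
            continue
        accepted.append(ev)
    times = np.sort([ev.scission_time for ev in accepted])

    def cumulative(t):
        return np.searchsorted(times, np.asarray(t, dtype=float), side="right")

    return {
        "events": accepted,
        "cut_times": times,
        "cumulative": cumulative,
        "fission_times": np.array([ev.fission_time for ev in accepted]),
    }


def remodeling_probability(tubes, bin_edges) -> dict:
    """Per-size-bin remodeling and fission probabilities with 95% CIs.

    ``tubes`` is a sequence of (starting_radius_nm, remodeled, cut)
    triples.  Empty bins carry NaN probabilities and are flagged.
    """
    from statsmodels.stats.proportion import proportion_confint

    edges = np.asarray(bin_edges, dtype=float)
    nb = len(edges) - 1
    out = {
        "bin_edges": edges,
        "n": np.zeros(nb, dtype=int),
        "p_remodeled": np.full(nb, np.nan),
        "p_cut": np.full(nb, np.nan),
        "ci_remodeled": np.full((nb, 2), np.nan),
        "ci_cut": np.full((nb, 2), np.nan),
        "empty": np.ones(nb, dtype=bool),
    }
    radii = np.array([t[0] for t in tubes], dtype=float)
    rem = np.array([bool(t[1]) for t in tubes])
    cut = np.array([bool(t[2]) for t in tubes])
    which = np.digitize(radii, edges) - 1
    for b in range(nb):
        sel = which == b
        n = int(np.sum(sel))
        out["n"][b] = n
        if n == 0:
            continue
        out["empty"][b] = False
        for key, flags in (("remodeled", rem[sel]), ("cut", cut[sel])):
            k = int(np.sum(flags))
            out[f"p_{key}"][b] = k / n
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            out[f"ci_{key}"][b] = (lo, hi)
    return out


# ----------------------------------------------------------------------
# FRAP
# ----------------------------------------------------------------------

def fit_frap(trace: FrapTrace, model: str = "hyperbolic") -> FrapFit:
    """Fit a FRAP recovery and report the mobile fraction and half-time.

    The default model-independent empirical form is a hyperbolic
    recovery,

        F(t) = F_b + (F_inf - F_b) * t / (t_half + t),

    with mobile fraction (F_inf - F_b) / (F_p - F_b).  An exponential
    recovery F(t) = F_inf - (F_inf - F_b) exp(-ln 2 t / t_half) is
    available with ``model='exponential'``.
    """
    fp = trace.f_prebleach
    fb = trace.f_bleach
    if not fb < fp:
        raise ValueError("no bleach: F_b must be below F_p")
    if len(trace.times) < 10:
        raise ValueError("need at least 10 post-bleach points")
    t = trace.times - trace.times[0]
    y = trace.recovery

    if model == "hyperbolic":
        def f(t, f_inf, t_half):
            return fb + (f_inf - fb) * t / (t_half + t)
    elif model == "exponential":
        def f(t, f_inf, t_half):
            return f_inf - (f_inf - fb) * np.exp(-np.log(2.0) * t / t_half)
    else:
        raise ValueError(f"unknown FRAP model: {model}")

    t_span = max(t[-1], 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            f, t, y,
            p0=[0.5 * (fp + fb), 0.2 * t_span],
            bounds=([fb, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
        raise RuntimeError(f"FRAP fit did not converge (rms residual {resid:.3g})") from err
    f_inf, t_half = popt
    resid = float(np.sqrt(np.mean((y - f(t, *popt)) ** 2)))
    mf = (f_inf - fb) / (fp - fb)
    return FrapFit(
        mobile_fraction=float(mf),
        half_time=float(t_half),
        f_inf=float(f_inf),
        residual=resid,
        model=model,
    )


# ----------------------------------------------------------------------
# kymograph growth rate
# ----------------------------------------------------------------------

def scaffold_growth_rate(
    kymograph,
    pixel_size: float,
    frame_interval: float = 1.0,
    threshold: float | None = None,
    min_motion: float = 1.0,
) -> GrowthRate:
    """Scaffold growth rate (nm/s) from a kymograph (time x position).

    The scaffold edge in each line is the rightmost position whose
    intensity exceeds the half-range threshold; the rate is the
    Theil-Sen slope of edge position against time (robust to outlier
    lines).  If total edge motion is below ``min_motion`` pixels the
    rate is 0 with ``low_confidence`` set.
    """
    kymo = np.asarray(kymograph, dtype=float)
    if kymo.ndim != 2 or kymo.shape[0] < 3:
        raise ValueError("kymograph must be 2-D with >= 3 time lines")
    if threshold is None:
        threshold = 0.5 * (kymo.max() + kymo.min())
    edges = np.full(kymo.shape[0], np.nan)
    for row in range(kymo.shape[0]):
        above = np.flatnonzero(kymo[row] > threshold)
        if above.size:
            edges[row] = above[-1]
    ok = ~np.isnan(edges)
    if np.sum(ok) < 3:
        return GrowthRate(rate=0.0, intercept=np.nan, low_confidence=True)
    t = np.flatnonzero(ok) * frame_interval
    e = edges[ok] * pixel_size
    slope, intercept, _, _ = stats.theilslopes(e, t)
    # an edge whose fitted net motion over the whole kymograph is below
    # min_motion pixels is static (pixel jitter notwithstanding)
    if abs(slope) * (t[-1] - t[0]) < min_motion * pixel_size:
        return GrowthRate(rate=0.0, intercept=float(e[0]), low_confidence=True)
    return GrowthRate(rate=float(slope), intercept=float(intercept))


# ----------------------------------------------------------------------
# movie-level pipeline
# ----------------------------------------------------------------------

@dataclass
class MovieAnalysis:
    """Detected remodeling events of one tube movie."""

    bulges: list = field(default_factory=list)        # final-frame BulgeRecord
    onsets: dict = field(default_factory=dict)        # position (nm) -> onset time (s)
    scission_time: float | None = None
    scission_position: float | None = None
    radius_profiles: np.ndarray | None = None         # (T, W) nm


def movie_peak_traces(movie: TubeMovie) -> np.ndarray:
    """Background-corrected per-frame axial peak-intensity traces (T, W)."""
    return np.maximum(movie.frames.max(axis=1) - movie.background, 0.0)


def analyze_remodeling_movie(
    movie: TubeMovie,
    k2: float,
    baseline_window: float = 5000.0,
    threshold_fraction: float = 0.20,
    merge_distance: float = 200.0,
    gap_radius: float = 2.0,
    min_gap: float = 300.0,
) -> MovieAnalysis:
    """Track bulge onsets and scission on a (membrane-channel) tube movie.

    Per frame, the peak-intensity trace is converted to a radius profile
    (k2 route); bulge onsets are the first frames at which the bulge
    criterion fires at a given position; scission is the first frame
    with a contiguous run wider than ``min_gap`` (nm) whose radius falls
    below ``gap_radius`` (nm).
    """
    traces = movie_peak_traces(movie)
    profiles = traces / k2
    out = MovieAnalysis(radius_profiles=profiles)
    px = movie.pixel_size

    for f in range(movie.n_frames):
        r = profiles[f]
        # scission: wide run of near-zero radius
        low = r < gap_radius
        idx = np.flatnonzero(low)
        if idx.size:
            splits = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, splits + 1):
                if len(run) * px >= min_gap:
                    if out.scission_time is None:
                        out.scission_time = float(movie.times[f])
                        out.scission_position = float(np.mean(run) * px)
                    break
        if out.scission_time is not None:
            break
        try:
            bulges, _ = detect_bulges(
                r, px, baseline_window, threshold_fraction, merge_distance
            )
        except ValueError:
            continue
        out.bulges = bulges
        for b in bulges:
            key = round(b.position / merge_distance)
            if key not in out.onsets:
                out.onsets[key] = float(movie.times[f])
                b.onset_time = float(movie.times[f])
    return out
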