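"""Ground-truth fluorescence data generators: SLBs, tubes, remodeling
movies, FRAP traces, kymographs.

The generators emulate the imaging physics the morphometry stage relies
on: the brightness of a diffraction-limited membrane tube is
proportional to the net membrane area inside the focal volume, so a tube
of radius r contributes line intensity proportional to 2*pi*r per unit
length; an SLB contributes a uniform area density.  Images are blurred
with an isotropic Gaussian PSF and carry Poisson-Gaussian noise.  Every
generator is deterministic given its seed and emits exact ground truth
for detector tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .morphometry import FrapTrace, TubeMovie


@dataclass
class RenderConfig:
    """Imaging model parameters shared by all renders."""

    pixel_size: float = 80.0         # nm per pixel
    psf_sigma: float = 120.0         # nm, isotropic Gaussian PSF
    brightness: float = 50.0         # a.u. per nm^2 of membrane
    background: float = 100.0        # a.u. offset
    gain: float = 2.0                # a.u. per photon (Poisson scaling)
    read_noise: float = 2.0          # a.u. rms Gaussian
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.psf_sigma <= 0 or self.brightness <= 0:
            raise ValueError("pixel size, PSF width and brightness must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _add_noise(signal: np.ndarray, cfg: RenderConfig, rng) -> np.ndarray:
    """Poisson-Gaussian camera noise on top of a noise-free signal."""
    if cfg.gain > 0:
        out = rng.poisson(np.maximum(signal, 0.0) / cfg.gain) * cfg.gain
    else:
        out = signal.copy()
    if cfg.read_noise > 0:
        out = out + rng.normal(0.0, cfg.read_noise, signal.shape)
    return out


def _blur(img: np.ndarray, cfg: RenderConfig) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img, sigma=cfg.psf_sigma / cfg.pixel_size, mode="nearest")


def render_slb(density: float, shape: tuple, cfg: RenderConfig, rng=None) -> np.ndarray:
    """Uniform supported lipid bilayer: density (a.u. per nm^2) times the
    pixel area, plus background and noise."""
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = cfg.rng() if rng is None else rng
    signal = np.full(shape, density * cfg.pixel_size**2, dtype=float)
    return _add_noise(signal, cfg, rng) + cfg.background


def render_tube(
    radius_profile: np.ndarray,
    cfg: RenderConfig,
    height: int | None = None,
    rng=None,
    noise: bool = True,
) -> np.ndarray:
    """Render a horizontal tube with the given per-pixel radius profile.

    Each axial pixel deposits brightness * 2*pi*r(x) * pixel_size on the
    tube center line (membrane area per axial length projected into the
    focal volume); the image is then PSF-blurred, and background plus
    camera noise are added.  The PSF preserves integrated density, so
    the k1 route recovers r(x) from ROI sums.
    """
    r = np.asarray(radius_profile, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius profile must be >= 0")
    if height is None:
        height = int(np.ceil(8 * cfg.psf_sigma / cfg.pixel_size)) | 1
    if np.any(2.0 * r > height * cfg.pixel_size):
        raise ValueError("tube radius exceeds the rendered field of view")
    rng = cfg.rng() if rng is None else rng
    img = np.zeros((height, len(r)))
    img[height // 2, :] = cfg.brightness * 2.0 * np.pi * r * cfg.pixel_size
    img = _blur(img, cfg)
    if noise:
        img = _add_noise(img, cfg, rng)
    return img + cfg.background


def render_slb_and_tubes(
    slb_density_scale: float,
    tube_radii,
    cfg: RenderConfig,
    shape=(64, 64),
):
    """Convenience: one SLB image plus tube images sharing the brightness
    constant — the matched calibration set for the k1/k2 pipeline."""
    rng = cfg.rng()
    slb = render_slb(cfg.brightness * slb_density_scale, shape, cfg, rng=rng)
    tubes = [
        render_tube(np.full(shape[1], float(r)), cfg, rng=rng) for r in tube_radii
    ]
    return slb, tubes


# ----------------------------------------------------------------------
# remodeling movies
# ----------------------------------------------------------------------

@dataclass
class ScaffoldSite:
    """Ground-truth scaffold on a synthetic tube."""

    position: float                  # nm
    nucleation_time: float           # s
    bulge_ratio: float = 1.5         # bulged radius / baseline
    width: float = 400.0             # nm, Gaussian bulge width (sigma)


@dataclass
class GroundTruthLog:
    """Exact event log emitted alongside a remodeling movie."""

    onsets: dict = field(default_factory=dict)        # site position -> s
    scission_time: float | None = None
    scission_position: float | None = None
    area_per_frame: np.ndarray | None = None          # integral r dx, nm^2
    radius_profiles: np.ndarray | None = None         # (T, W) nm
    infeasible: bool = False

    def to_json(self) -> str:
        d = {
            "onsets": {f"{k:.1f}": v for k, v in self.onsets.items()},
            "scission_time": self.scission_time,
            "scission_position": self.scission_position,
            "infeasible": self.infeasible,
        }
        return json.dumps(d)


def simulate_remodeling_movie(
    tube_length: float,
    baseline_radius: float,
    scaffold_sites: list[ScaffoldSite],
    growth_rate: float,
    fission_radius: float,
    cfg: RenderConfig,
    n_frames: int = 60,
    frame_interval: float = 1.0,
    onset_threshold: float = 0.20,
    retraction_speed: float = 500.0,
) -> tuple[TubeMovie, GroundTruthLog]:
    """Simulate scaffold-driven bulging with area-conserving thinning.

    Each scaffold grows axially at ``growth_rate`` (nm/s) from its
    nucleation time, holding its bulged radius; the membrane area
    integral (2*pi * integral of r dx) is held constant by uniformly
    thinning the regions outside the scaffolds (the finite-reservoir
    constraint of a tube with fixed ends).  When the thinned radius
    reaches ``fission_radius`` a scission event is logged in the widest
    inter-scaffold gap, after which the cut ends retract and leave
    bright puncta.  The logged onset per scaffold is the first frame at
    which its bulge exceeds the onset threshold over baseline — the same
    operational criterion the detector uses.

    Remodeling scenarios presume a baseline radius below 25 nm; larger
    tubes are rendered but flagged infeasible for remodeling.
    """
    if baseline_radius >= 25.0:
        import warnings

        warnings.warn("baseline radius >= 25 nm: tubes this wide are not "
                      "remodeled in the scenario this generator emulates",
                      stacklevel=2)
    rng = cfg.rng()
    n_px = int(round(tube_length / cfg.pixel_size))
    x = (np.arange(n_px) + 0.5) * cfg.pixel_size
    times = np.arange(n_frames) * frame_interval

    area0 = baseline_radius * tube_length          # integral r dx (per 2*pi)
    log = GroundTruthLog(onsets={}, area_per_frame=np.zeros(n_frames))
    profiles = np.zeros((n_frames, n_px))
    frames = np.zeros((n_frames, int(np.ceil(8 * cfg.psf_sigma / cfg.pixel_size)) | 1, n_px))

    ramp_time = 2.0 * frame_interval               # bulge rise time after nucleation
    for f, t in enumerate(times):
        if log.scission_time is not None:
            # post-scission: retract the cut ends, bright puncta at tips
            dt_post = t - log.scission_time
            half_gap = 300.0 + retraction_speed * dt_post
            r = profiles[f - 1].copy()
            gap = np.abs(x - log.scission_position) < half_gap
            r[gap] = 0.0
            profiles[f] = r
            img = np.zeros_like(frames[f])
            img[img.shape[0] // 2, :] = cfg.brightness * 2.0 * np.pi * r * cfg.pixel_size
            for tip in (log.scission_position - half_gap, log.scission_position + half_gap):
                k = int(round(tip / cfg.pixel_size))
                if 0 <= k < n_px:
                    img[img.shape[0] // 2, k] += cfg.brightness * 2.0 * np.pi * (
                        3.0 * baseline_radius * cfg.pixel_size
                    )
            img = _blur(img, cfg)
            frames[f] = _add_noise(img, cfg, rng) + cfg.background
            log.area_per_frame[f] = np.nan
            continue

        # scaffold coverage and bulge shape
        bulge = np.zeros(n_px)
        covered = np.zeros(n_px, dtype=bool)
        for site in scaffold_sites:
            if t < site.nucleation_time:
                continue
            grown = growth_rate * (t - site.nucleation_time)
            half_len = 0.5 * max(grown, 1.0)
            ramp = min(1.0, (t - site.nucleation_time) / ramp_time) if ramp_time > 0 else 1.0
            amp = (site.bulge_ratio - 1.0) * baseline_radius * ramp
            inside = np.abs(x - site.position) < half_len
            shoulder = np.exp(-0.5 * ((np.abs(x - site.position) - half_len) / site.width) ** 2)
            shape = np.where(inside, 1.0, shoulder)
            bulge = np.maximum(bulge, amp * shape)
            covered |= inside
            if amp >= onset_threshold * baseline_radius and site.position not in log.onsets:
                log.onsets[site.position] = float(t)

        # area-conserving thinning of the uncovered regions
        demand = np.sum(bulge) * cfg.pixel_size
        free_len = np.sum(~covered) * cfg.pixel_size
        if free_len <= 0:
            log.infeasible = True
            profiles = profiles[: f + 1]
            frames = frames[: f + 1]
            times = times[: f + 1]
            break
        thin = demand / free_len
        r_far = baseline_radius - thin
        if r_far < 0:
            log.infeasible = True
            profiles = profiles[: f + 1]
            frames = frames[: f + 1]
            times = times[: f + 1]
            break
        r = np.where(covered, baseline_radius + bulge, baseline_radius + bulge - thin)
        # exact area conservation (discrete correction on the free region)
        corr = (area0 - np.sum(r) * cfg.pixel_size) / free_len
        r[~covered] += corr
        profiles[f] = r
        log.area_per_frame[f] = np.sum(r) * cfg.pixel_size

        if r_far <= fission_radius and np.any(~covered):
            # scission in the widest uncovered run
            idx = np.flatnonzero(~covered)
            splits = np.flatnonzero(np.diff(idx) > 1)
            runs = np.split(idx, splits + 1)
            widest = max(runs, key=len)
            log.scission_time = float(t)
            log.scission_position = float(x[widest[len(widest) // 2]])
            r = r.copy()
            gap = np.abs(x - log.scission_position) < 300.0
            r[gap] = 0.0
            profiles[f] = r

        img = np.zeros_like(frames[f])
        img[img.shape[0] // 2, :] = cfg.brightness * 2.0 * np.pi * profiles[f] * cfg.pixel_size
        img = _blur(img, cfg)
        frames[f] = _add_noise(img, cfg, rng) + cfg.background

    movie = TubeMovie(
        frames=frames,
        pixel_size=cfg.pixel_size,
        times=times,
        channel="membrane",
        background=cfg.background,
    )
    log.radius_profiles = profiles
    return movie, log


# ----------------------------------------------------------------------
# paired protein/membrane channels (scaffold sign scenarios)
# ----------------------------------------------------------------------

def render_scaffold_tube_pair(
    kind: str,
    cfg: RenderConfig,
    tube_length: float = 10000.0,
    baseline_radius: float = 12.0,
    n_scaffolds: int = 3,
    effect: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Membrane and protein traces of a tube carrying scaffolds that
    either bulge (``kind='bulge'``) or constrict (``kind='constriction'``)
    the underlying tube.

    Returns background-corrected peak-intensity traces (membrane,
    protein) sampled along the tube — the inputs of the Pearson
    protein-membrane analysis.
    """
    if kind not in ("bulge", "constriction"):
        raise ValueError("kind must be 'bulge' or 'constriction'")
    rng = cfg.rng()
    n_px = int(round(tube_length / cfg.pixel_size))
    x = (np.arange(n_px) + 0.5) * cfg.pixel_size
    r = np.full(n_px, baseline_radius)
    protein = np.zeros(n_px)
    margin = tube_length / (n_scaffolds + 1)
    width = 300.0
    sgn = 1.0 if kind == "bulge" else -1.0
    for k in range(n_scaffolds):
        pos = margin * (k + 1) + rng.uniform(-0.2, 0.2) * margin
        prof = np.exp(-0.5 * ((x - pos) / width) ** 2)
        r = r + sgn * effect * baseline_radius * prof
        protein = protein + prof
    mem_img = render_tube(r, cfg, rng=rng)
    mem_trace = mem_img.max(axis=0) - cfg.background
    prot_img = np.zeros_like(mem_img)
    prot_img[prot_img.shape[0] // 2, :] = 1000.0 * protein
    prot_img = _blur(prot_img, cfg)
    prot_trace = (_add_noise(prot_img, cfg, rng)).max(axis=0)
    return mem_trace, prot_trace


# ----------------------------------------------------------------------
# FRAP and kymographs
# ----------------------------------------------------------------------

def simulate_frap_trace(
    f_prebleach: float,
    f_bleach: float,
    mobile_fraction: float,
    half_time: float,
    n_points: int = 60,
    frame_interval: float = 0.5,
    noise: float = 0.01,
    seed: int = 0,
) -> FrapTrace:
    """Hyperbolic FRAP recovery toward F_b + mf*(F_p - F_b), plus
    Gaussian noise of rms ``noise * F_p``."""
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile fraction must be in [0, 1]")
    if f_bleach > f_prebleach:
        raise ValueError("F_b must not exceed F_p")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * frame_interval
    f_inf = f_bleach + mobile_fraction * (f_prebleach - f_bleach)
    y = f_bleach + (f_inf - f_bleach) * t / (half_time + t)
    y = y + rng.normal(0.0, noise * f_prebleach, n_points)
    y[0] = f_bleach
    return FrapTrace(f_prebleach=f_prebleach, times=t, recovery=y)


def simulate_kymograph(
    edge_speed: float,
    duration: float,
    cfg: RenderConfig,
    length: float = 4000.0,
    line_interval: float = 0.2,
    start_position: float = 200.0,
    amplitude: float = 1000.0,
) -> np.ndarray:
    """Kymograph (time x position) of a bright wedge whose edge advances
    at ``edge_speed`` (nm/s); speed 0 gives a vertical edge."""
    if edge_speed < 0:
        raise ValueError("edge speed must be >= 0")
    rng = cfg.rng()
    n_lines = int(round(duration / line_interval))
    n_px = int(round(length / cfg.pixel_size))
    x = (np.arange(n_px) + 0.5) * cfg.pixel_size
    kymo = np.zeros((n_lines, n_px))
    for row in range(n_lines):
        edge = start_position + edge_speed * row * line_interval
        kymo[row] = amplitude / (1.0 + np.exp((x - edge) / (0.3 * cfg.pixel_size)))
    from scipy.ndimage import gaussian_filter1d

    kymo = gaussian_filter1d(kymo, cfg.psf_sigma / cfg.pixel_size, axis=1, mode="nearest")
    return _add_noise(kymo, cfg, rng) + cfg.background


# ----------------------------------------------------------------------
# file output
# ----------------------------------------------------------------------

def write_movie(movie: TubeMovie, log: GroundTruthLog | None, path_prefix: str) -> None:
    """Write a movie as multi-page TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    tifffile.imwrite(path_prefix + ".tif", movie.frames.astype(np.float32))
    if log is not None:
        with open(path_prefix + "_truth.json", "w") as fh:
            fh.write(log.to_json())
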