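"""Synthetic fluorescence-microscopy generator with known ground truth.

Emulates the imaging regimes of developing hippocampal neurons in culture:
a soma with curvilinear neurites imaged at 0.15-0.44 um/pixel and 20-180 s
frame intervals; photoconverted tubulin patches drifting toward the soma at
~0.2-1 um/min; CAMSAP3 puncta moving retrogradely; EB3 comets at
12-18 um/min in mixed orientations; frame-to-frame translation jitter;
Poisson + Gaussian noise; and exponential bleaching.

Every generator threads all randomness through one seeded
``numpy.random.Generator``, so an identical :class:`SimConfig` produces
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Kymograph, MovieStack, NeuritePath, Track

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_patch_movie",
    "simulate_camsap_movie",
    "simulate_comet_tracks",
    "simulate_density_traces",
    "simulate_mass_kymograph",
]

_PATH_STEP_PX = 0.25  # fine sampling step used when rendering along paths


@dataclass
class SimConfig:
    """Parameters of a synthetic imaging experiment.

    Spatial units are micrometres unless the name says pixels; speeds are
    um/min with retrograde (soma-ward) drift negative along the arc length.
    """

    shape: tuple[int, int] = (240, 240)
    pixel_size_um: float = 0.22
    frame_interval_s: float = 30.0
    n_frames: int = 21
    seed: int = 0

    # geometry
    n_neurites: int = 1
    neurite_length_um: float = 20.0
    curvature_rad_per_um: float = 0.02
    neurite_sigma_px: float = 1.5  # Gaussian cross-section of rendered neurites
    neurite_amplitude: float = 80.0
    soma_radius_um: float = 5.0
    soma_amplitude: float = 150.0
    background_level: float = 10.0

    # photoconverted / photoactivated patches
    patch_init_um: tuple[float, ...] = (14.0,)
    patch_speed_um_min: tuple[float, ...] = (-0.53,)
    patch_neurite: tuple[int, ...] = (0,)
    patch_sigma_um: float = 1.0  # longitudinal extent of the converted patch
    patch_amplitude: float = 100.0

    # CAMSAP3 puncta
    camsap_n_puncta: int = 6
    camsap_speed_um_min: float | tuple[float, ...] = -0.4
    camsap_sigma_px: float = 1.2
    camsap_amplitude: float = 120.0
    camsap_slowdown_frame: int | None = None
    camsap_slowdown_factor: float = 0.5
    camsap_slowdown_neurite: int = 0

    # EB3 comets
    comet_n: int = 100
    comet_speed_range_um_min: tuple[float, float] = (12.0, 18.0)
    comet_frame_interval_s: float = 1.0
    comet_len_frames: tuple[int, int] = (5, 15)

    # acquisition imperfections
    jitter_max_px: int = 0
    jitter_subpixel: bool = False
    noise_gaussian_sd: float = 0.0
    poisson_gain: float = 0.0  # photons per intensity unit; 0 disables shot noise
    bleach_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("patch_init_um", "patch_speed_um_min", "patch_neurite"):
            v = getattr(self, name)
            if np.isscalar(v):
                setattr(self, name, (v,))
            else:
                setattr(self, name, tuple(v))
        n = len(self.patch_init_um)
        if len(self.patch_speed_um_min) != n:
            raise ValueError("patch_init_um and patch_speed_um_min lengths differ")
        if len(self.patch_neurite) != n:
            self.patch_neurite = tuple(
                self.patch_neurite[i % len(self.patch_neurite)] for i in range(n)
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Carrier of the exact quantities a recovery test compares against."""

    paths: list[NeuritePath] = field(default_factory=list)
    jitter_px: np.ndarray | None = None  # (T, 2) applied (dy, dx) per frame
    patch_arclen_um: np.ndarray | None = None  # (n_patches, T)
    patch_xy: np.ndarray | None = None  # (n_patches, T, 2), scene coords (no jitter)
    patch_speed_um_min: np.ndarray | None = None  # signed, negative = retrograde
    patch_neurite: np.ndarray | None = None
    puncta: list[dict] = field(default_factory=list)
    slowdown_onset_min: float | None = None
    comet_labels: list[str] = field(default_factory=list)
    density_period_h: float | None = None
    density_amplitude: float | None = None
    density_phases: np.ndarray | None = None
    true_cycles_per_hour: float | None = None
    true_full_cycles: float | None = None
    mass_fractions: tuple[float, float, float] | None = None
    mass_start_px: int | None = None
    mass_background: float | None = None


# ---------------------------------------------------------------------------
# geometry and rendering helpers
# ---------------------------------------------------------------------------

def make_neurite_paths(config: SimConfig, rng: np.random.Generator) -> list[NeuritePath]:
    """Curvilinear neurite center lines radiating from the image center.

    Headings follow a small random walk (curvature) and are steered back
    toward the image center when a path approaches the border.
    """
    h, w = config.shape
    center = np.array([h / 2.0, w / 2.0])
    margin = 6.0
    px = config.pixel_size_um
    soma_r_px = config.soma_radius_um / px
    base_angles = (
        2 * np.pi * (np.arange(config.n_neurites) / config.n_neurites)
        + rng.uniform(0, 2 * np.pi)
    )
    n_steps = int(np.ceil(config.neurite_length_um / (px * _PATH_STEP_PX)))
    paths = []
    for i, theta0 in enumerate(base_angles):
        theta = float(theta0)
        pos = center + soma_r_px * np.array([np.sin(theta), np.cos(theta)])
        pts = [pos.copy()]
        for _ in range(n_steps):
            theta += rng.normal(0.0, config.curvature_rad_per_um * px * _PATH_STEP_PX)
            nxt = pts[-1] + _PATH_STEP_PX * np.array([np.sin(theta), np.cos(theta)])
            if (
                nxt[0] < margin
                or nxt[0] > h - margin
                or nxt[1] < margin
                or nxt[1] > w - margin
            ):
                # steer back toward the center
                back = center - pts[-1]
                theta = float(np.arctan2(back[0], back[1]))
                nxt = pts[-1] + _PATH_STEP_PX * np.array([np.sin(theta), np.cos(theta)])
            pts.append(nxt)
        paths.append(NeuritePath(np.array(pts), px, neurite_id=i))
    return paths


def _deposit(shape: tuple[int, int], points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Accumulate weights at subpixel (y, x) points by bilinear splatting
    (nearest-pixel rounding would bias centroids of near-axis-aligned
    structures by up to half a pixel)."""
    img = np.zeros(shape, dtype=float)
    y = np.clip(points[:, 0], 0.0, shape[0] - 1.001)
    x = np.clip(points[:, 1], 0.0, shape[1] - 1.001)
    y0 = np.floor(y).astype(int)
    x0 = np.floor(x).astype(int)
    fy = y - y0
    fx = x - x0
    np.add.at(img, (y0, x0), weights * (1 - fy) * (1 - fx))
    np.add.at(img, (y0 + 1, x0), weights * fy * (1 - fx))
    np.add.at(img, (y0, x0 + 1), weights * (1 - fy) * fx)
    np.add.at(img, (y0 + 1, x0 + 1), weights * fy * fx)
    return img


def render_base_frame(config: SimConfig, paths: list[NeuritePath]) -> np.ndarray:
    """Static soma + neurite scene (the cytosolic / whole-tubulin channel)."""
    h, w = config.shape
    yy, xx = np.mgrid[0:h, 0:w]
    center = np.array([h / 2.0, w / 2.0])
    r_px = config.soma_radius_um / config.pixel_size_um
    soma = (np.hypot(yy - center[0], xx - center[1]) <= r_px).astype(float)
    img = config.soma_amplitude * ndimage.gaussian_filter(soma, 1.0)
    for path in paths:
        line = _deposit(config.shape, path.points, np.full(len(path.points), 1.0))
        line = np.minimum(line, 1.0)  # 1-px-wide center line, then diffraction blur
        blurred = ndimage.gaussian_filter(line, config.neurite_sigma_px)
        peak = blurred.max()
        if peak > 0:
            img += config.neurite_amplitude * blurred / peak
    return img


def _gaussian_blob(
    shape: tuple[int, int],
    path: NeuritePath,
    s_um: float,
    sigma_um: float,
    sigma_px: float,
    total: float,
) -> np.ndarray:
    """A patch rendered along the path: Gaussian in arc length, then blurred
    transversally. The blob is renormalized so its summed intensity is
    exactly ``total`` (mass conservation when bleaching and noise are off)."""
    s = path.arclen_um
    wts = np.exp(-0.5 * ((s - s_um) / sigma_um) ** 2)
    img = _deposit(shape, path.points, wts)
    img = ndimage.gaussian_filter(img, sigma_px)
    ssum = img.sum()
    if ssum > 0:
        img *= total / ssum
    return img


def _apply_jitter(frame: np.ndarray, shift: np.ndarray, subpixel: bool) -> np.ndarray:
    if subpixel:
        return ndimage.shift(frame, shift, order=1, mode="grid-wrap")
    return np.roll(frame, (int(shift[0]), int(shift[1])), axis=(0, 1))


def _apply_noise(
    frame: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    out = frame
    if config.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * config.poisson_gain) / config.poisson_gain
    if config.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, config.noise_gaussian_sd, size=frame.shape)
    return out


def _draw_jitter(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    jit = np.zeros((config.n_frames, 2))
    if config.jitter_max_px > 0:
        if config.jitter_subpixel:
            jit[1:] = rng.uniform(
                -config.jitter_max_px, config.jitter_max_px, size=(config.n_frames - 1, 2)
            )
        else:
            jit[1:] = rng.integers(
                -config.jitter_max_px, config.jitter_max_px + 1, size=(config.n_frames - 1, 2)
            )
    return jit


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_patch_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Photoconversion pulse-chase movie: a whole-tubulin channel plus a
    converted-patch channel in which each patch drifts along its neurite at
    the configured signed speed (negative = toward the soma).

    The ground truth records the exact per-frame patch arc-length position.
    """
    rng = config.rng()
    paths = make_neurite_paths(config, rng)
    for init, ni in zip(config.patch_init_um, config.patch_neurite):
        if init > paths[ni].length_um:
            raise ValueError(
                f"patch initial position {init} um exceeds neurite length "
                f"{paths[ni].length_um:.2f} um"
            )
    n_patches = len(config.patch_init_um)
    t_min = np.arange(config.n_frames) * config.frame_interval_s / 60.0
    jitter = _draw_jitter(config, rng)
    base = render_base_frame(config, paths)
    sigma_total = config.patch_amplitude * (
        2 * np.pi * (config.patch_sigma_um / config.pixel_size_um) * config.neurite_sigma_px
    )

    arclen = np.zeros((n_patches, config.n_frames))
    xy = np.zeros((n_patches, config.n_frames, 2))
    tub = np.zeros((config.n_frames, *config.shape))
    conv = np.zeros_like(tub)
    for t in range(config.n_frames):
        bleach = np.exp(-config.bleach_rate_per_min * t_min[t])
        frame_c = np.zeros(config.shape)
        for p in range(n_patches):
            path = paths[config.patch_neurite[p]]
            s = config.patch_init_um[p] + config.patch_speed_um_min[p] * t_min[t]
            s = float(np.clip(s, 0.2, path.length_um - 0.2))
            arclen[p, t] = s
            xy[p, t] = path.point_at_arclen(s)
            frame_c += _gaussian_blob(
                config.shape, path, s, config.patch_sigma_um,
                config.neurite_sigma_px, sigma_total,
            )
        frame_t = config.background_level + base * bleach
        frame_c = frame_c * bleach
        frame_t = _apply_jitter(frame_t, jitter[t], config.jitter_subpixel)
        frame_c = _apply_jitter(frame_c, jitter[t], config.jitter_subpixel)
        tub[t] = _apply_noise(frame_t, config, rng)
        conv[t] = _apply_noise(frame_c, config, rng)

    movie = MovieStack(
        np.stack([tub, conv]),
        config.pixel_size_um,
        config.frame_interval_s,
        ("tubulin", "converted"),
    )
    truth = GroundTruth(
        paths=paths,
        jitter_px=jitter,
        patch_arclen_um=arclen,
        patch_xy=xy,
        patch_speed_um_min=np.asarray(config.patch_speed_um_min, dtype=float),
        patch_neurite=np.asarray(config.patch_neurite, dtype=int),
    )
    return movie, truth


def simulate_camsap_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Movie of point-like CAMSAP3 puncta drifting somatally along neurites.

    Puncta appear at staggered frames and distal positions so that traces
    cover the whole movie. When ``camsap_slowdown_frame`` is set, puncta on
    ``camsap_slowdown_neurite`` move at ``camsap_slowdown_factor`` times
    their speed from that frame on; the ground truth records the onset.
    """
    if config.camsap_n_puncta < 1:
        raise ValueError("need at least one punctum per neurite")
    rng = config.rng()
    paths = make_neurite_paths(config, rng)
    jitter = _draw_jitter(config, rng)
    speeds = config.camsap_speed_um_min
    if np.isscalar(speeds):
        speeds = tuple([float(speeds)] * config.n_neurites)

    t_min_all = np.arange(config.n_frames) * config.frame_interval_s / 60.0
    puncta = []
    for ni, path in enumerate(paths):
        for k in range(config.camsap_n_puncta):
            start_frame = int(
                rng.integers(0, max(1, config.n_frames - 3))
            ) if k > 0 else 0
            s0 = float(rng.uniform(0.4, 0.95) * path.length_um)
            pos = np.full(config.n_frames, np.nan)
            s = s0
            for t in range(start_frame, config.n_frames):
                if t > start_frame:
                    v = speeds[ni]
                    if (
                        config.camsap_slowdown_frame is not None
                        and ni == config.camsap_slowdown_neurite
                        and t > config.camsap_slowdown_frame
                    ):
                        v *= config.camsap_slowdown_factor
                    s += v * (t_min_all[t] - t_min_all[t - 1])
                if s < 0.5 or s > path.length_um - 0.3:
                    break
                pos[t] = s
            puncta.append({"neurite": ni, "arclen_um": pos, "speed_um_min": speeds[ni]})

    base = render_base_frame(config, paths)
    frames = np.zeros((config.n_frames, *config.shape))
    for t in range(config.n_frames):
        bleach = np.exp(-config.bleach_rate_per_min * t_min_all[t])
        frame = config.background_level + 0.15 * base * bleach
        for pu in puncta:
            s = pu["arclen_um"][t]
            if np.isfinite(s):
                path = paths[pu["neurite"]]
                frame += _gaussian_blob(
                    config.shape, path, s, 2.5 * config.pixel_size_um,
                    config.camsap_sigma_px,
                    config.camsap_amplitude * 2 * np.pi * config.camsap_sigma_px**2,
                ) * bleach
        frame = _apply_jitter(frame, jitter[t], config.jitter_subpixel)
        frames[t] = _apply_noise(frame, config, rng)

    onset = None
    if config.camsap_slowdown_frame is not None:
        onset = config.camsap_slowdown_frame * config.frame_interval_s / 60.0
    movie = MovieStack(
        frames[None], config.pixel_size_um, config.frame_interval_s, ("camsap",)
    )
    truth = GroundTruth(
        paths=paths, jitter_px=jitter, puncta=puncta, slowdown_onset_min=onset
    )
    return movie, truth


def simulate_comet_tracks(
    config: SimConfig, fraction_plus_end_out: float
) -> tuple[list[Track], GroundTruth]:
    """EB3 comet tracks along neurite paths at 12-18 um/min.

    Each comet moves tip-ward (a plus-end-out microtubule) with probability
    ``fraction_plus_end_out``, soma-ward otherwise; the true label of every
    comet is stored in the ground truth.
    """
    if not 0.0 <= fraction_plus_end_out <= 1.0:
        raise ValueError("fraction_plus_end_out must be in [0, 1]")
    rng = config.rng()
    paths = make_neurite_paths(config, rng)
    dt_min = config.comet_frame_interval_s / 60.0
    tracks, labels = [], []
    for cid in range(config.comet_n):
        ni = int(rng.integers(0, config.n_neurites))
        path = paths[ni]
        tipward = bool(rng.random() < fraction_plus_end_out)
        speed = float(rng.uniform(*config.comet_speed_range_um_min))
        n_pts = int(rng.integers(config.comet_len_frames[0], config.comet_len_frames[1] + 1))
        travel = speed * dt_min * (n_pts - 1)
        lo, hi = 0.5, path.length_um - 0.5
        if tipward:
            s0 = float(rng.uniform(lo, max(lo + 1e-6, hi - travel)))
            s_series = s0 + speed * dt_min * np.arange(n_pts)
        else:
            s0 = float(rng.uniform(min(hi - 1e-6, lo + travel), hi))
            s_series = s0 - speed * dt_min * np.arange(n_pts)
        s_series = np.clip(s_series, 0.1, path.length_um - 0.1)
        pts = np.array([path.point_at_arclen(s) for s in s_series])
        tracks.append(
            Track(
                frames=np.arange(n_pts),
                points=pts,
                arclen_um=s_series,
                frame_interval_s=config.comet_frame_interval_s,
                pixel_size_um=config.pixel_size_um,
                entity_id=cid,
                neurite_id=ni,
            )
        )
        labels.append("plus_end_out" if tipward else "minus_end_out")
    truth = GroundTruth(paths=paths, comet_labels=labels)
    return tracks, truth


def simulate_density_traces(
    config: SimConfig,
    period_h: float,
    amplitude: float,
    duration_h: float = 10.0,
    noise_sd: float = 0.03,
    waveform: str = "triangle",
) -> tuple[list, GroundTruth]:
    """Per-neurite normalized microtubule density traces oscillating around 1.

    ``amplitude`` is the peak-to-trough excursion of the waveform (a trace
    swings between ``1 - amplitude/2`` and ``1 + amplitude/2``), matching
    the convention that a density change of >= 0.2 counts as half a cycle.
    True frequency is ``1 / period_h`` cycles per hour.
    """
    from .cycles import DensityTrace

    if period_h <= 0:
        raise ValueError("period_h must be > 0")
    rng = config.rng()
    dt_h = config.frame_interval_s / 3600.0
    n = int(round(duration_h / dt_h)) + 1
    t_h = np.arange(n) * dt_h
    phases = rng.uniform(0, 1, size=config.n_neurites)
    traces = []
    for i in range(config.n_neurites):
        u = (t_h / period_h + phases[i]) % 1.0
        if waveform == "triangle":
            wave = 1.0 - 4.0 * np.abs(u - 0.5)  # in [-1, 1]
        elif waveform == "sine":
            wave = np.sin(2 * np.pi * u)
        else:
            raise ValueError(f"unknown waveform {waveform!r}")
        values = 1.0 + 0.5 * amplitude * wave
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n)
        traces.append(
            DensityTrace(values=values, frame_interval_s=config.frame_interval_s, neurite_id=i)
        )
    truth = GroundTruth(
        density_period_h=period_h,
        density_amplitude=amplitude,
        density_phases=phases,
        true_cycles_per_hour=1.0 / period_h,
        true_full_cycles=duration_h / period_h,
    )
    return traces, truth


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def simulate_mass_kymograph(
    config: SimConfig,
    fractions: tuple[float, float, float],
    noise_sd: float = 0.3,
    row_mass: float = 2000.0,
) -> tuple[Kymograph, GroundTruth]:
    """Background-subtracted-analysis fixture: a kymograph whose mass in the
    three zones (beyond 1.1 um retrograde / within +-1.1 um / beyond 1.1 um
    anterograde of the start column) matches the requested fractions.

    Each zone's signal is a Gaussian column profile truncated to its zone,
    so the zone sums equal the requested fractions exactly before noise.
    """
    retro, stat, antero = fractions
    if abs(retro + stat + antero - 1.0) > 1e-6 or min(fractions) < -1e-12:
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = config.rng()
    px = config.pixel_size_um
    n_cols = max(80, int(config.neurite_length_um / px))
    n_rows = config.n_frames
    start = n_cols // 2
    half = _round_half_up(1.1 / px)
    cols = np.arange(n_cols)

    def zone_profile(center: float, sigma: float, mask: np.ndarray) -> np.ndarray:
        prof = np.exp(-0.5 * ((cols - center) / sigma) ** 2) * mask
        s = prof.sum()
        return prof / s if s > 0 else prof

    retro_mask = cols < start - half
    stat_mask = np.abs(cols - start) <= half
    antero_mask = cols > start + half
    profile = (
        retro * zone_profile(start - half - 15, 4.0, retro_mask)
        + stat * zone_profile(start, max(1.0, half / 3.0), stat_mask)
        + antero * zone_profile(start + half + 15, 4.0, antero_mask)
    ) * row_mass
    data = config.background_level + np.tile(profile, (n_rows, 1))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    kymo = Kymograph(
        data, pixel_size_um=px, frame_interval_s=config.frame_interval_s
    )
    truth = GroundTruth(
        mass_fractions=(retro, stat, antero),
        mass_start_px=start,
        mass_background=config.background_level,
    )
    return kymo, truth
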