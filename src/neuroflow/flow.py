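"""Quantification of microtubule retrograde flow (MT-RF).

Speeds come from two complementary measurements: the drift of
photoconverted/photoactivated tubulin patches along a neurite (patch
tracking), and the slopes of minus-end marker (CAMSAP3) traces in
kymographs. The module also detects the axon-specific slowdown of the
flow, classifies the polarization stage from neurite lengths, and
quantifies how a labeled microtubule patch spreads and how its mass
partitions into retrograde / stationary / anterograde zones around the
labeling site.

Sign conventions: retrograde (soma-ward) speeds are reported positive,
with the direction carried by a label; kymographs are soma-left, so
retrograde movement is leftward (decreasing column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Kymograph, MovieStack, Track
from .kymograph import sample_kymograph

__all__ = [
    "FlowConfig",
    "FlowMeasurement",
    "SlowdownResult",
    "KymoTrace",
    "SpreadResult",
    "track_patch",
    "speed_from_track",
    "patch_synchrony",
    "extract_camsap_traces",
    "camsap_flow_series",
    "detect_slowdown",
    "classify_axon",
    "neurite_background",
    "patch_spread",
    "mass_distribution",
]


@dataclass
class FlowConfig:
    min_track_min: float = 1.0  # patches traceable for <= 1 min are rejected
    smooth_window_min: float = 200.0
    slowdown_ratio: float = 0.8  # "20% slower"
    qualifying_fraction: float = 0.95
    qualifying_duration_min: float = 180.0
    stationary_half_um: float = 1.1
    spread_trim_fraction: float = 0.10
    row_stop_factor: float = 1.8  # mass-partition row limit without LatB
    row_stop_factor_latb: float = 1.3
    signal_factor: float = 1.3  # spread / patch-tracking row limit
    compare_others: str = "min"  # axon vs "min" or "mean" of other neurites
    search_halfwidth_um: float = 2.5  # patch follower search window
    centroid_halfwidth_um: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "min_track_min", "smooth_window_min", "qualifying_duration_min",
            "stationary_half_um", "signal_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("slowdown_ratio", "qualifying_fraction", "spread_trim_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class FlowMeasurement:
    neurite_id: int
    speed_um_min: float  # magnitude; direction carried by the label
    direction: str  # retrograde | anterograde | immobile
    duration_min: float
    method: str  # patch | camsap

    def __post_init__(self) -> None:
        if self.speed_um_min < 0:
            raise ValueError("speed magnitude must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class SlowdownResult:
    detected: bool
    onset_min: float | None
    axon_id: int
    evaluable: bool = True


@dataclass
class KymoTrace:
    """A linked punctum trace in a kymograph (frame index, column position)."""

    frames: np.ndarray
    pos_px: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.pos_px = np.asarray(self.pos_px, dtype=float)

    def speed_um_min(self, pixel_size_um: float, frame_interval_s: float) -> float:
        """Signed slope: positive = retrograde (toward soma, leftward)."""
        dur_min = (self.frames[-1] - self.frames[0]) * frame_interval_s / 60.0
        if dur_min <= 0:
            return 0.0
        return (self.pos_px[0] - self.pos_px[-1]) * pixel_size_um / dur_min


@dataclass
class SpreadResult:
    rows: np.ndarray  # analyzed row (time) indices
    spread_um: np.ndarray  # per analyzed row
    retro_speed_um_min: float
    antero_speed_um_min: float


# ---------------------------------------------------------------------------
# patch tracking and speeds
# ---------------------------------------------------------------------------

def track_patch(
    movie: MovieStack,
    path,
    config: FlowConfig | None = None,
    channel=0,
    start_um: float | None = None,
    width_px: int = 11,
    allow_multiple: bool = False,
) -> Track:
    """Follow a labeled microtubule patch along a neurite path.

    Per frame the patch position is the intensity-weighted centroid
    arc-length of the background-subtracted signal in the path corridor
    (background = per-row median of the corridor kymograph), restricted to
    a window around the previous position (or ``start_um`` in frame 0).
    The track ends when the peak signal falls below ``signal_factor`` times
    the background. With ``start_um`` unset, a corridor containing more
    than one patch raises unless ``allow_multiple`` is set.
    """
    if config is None:
        config = FlowConfig()
    kymo = sample_kymograph(movie, path, width_px=width_px, channel=channel)
    px = kymo.pixel_size_um
    cols = np.arange(kymo.n_positions)

    def row_signal(t: int) -> tuple[np.ndarray, float]:
        row = kymo.data[t]
        bg = float(np.median(row))
        return np.clip(row - bg, 0.0, None), bg

    sig0, bg0 = row_signal(0)
    if sig0.max() <= 0 or kymo.data[0].max() < config.signal_factor * max(bg0, 1e-12):
        raise ValueError("no patch signal above background in frame 0")
    if start_um is None and not allow_multiple:
        if _count_peaks(sig0, config, px) > 1:
            raise ValueError(
                "multiple patches in corridor; pass start_um per patch or "
                "allow_multiple=True"
            )

    frames, positions = [], []
    prev = start_um
    half_px = config.search_halfwidth_um / px
    cent_px = config.centroid_halfwidth_um / px
    for t in range(kymo.n_frames):
        sig, bg = row_signal(t)
        window = np.ones_like(sig, dtype=bool)
        if prev is not None:
            window = np.abs(cols - prev / px) <= half_px
        wsig = np.where(window, sig, 0.0)
        if wsig.max() <= 0:
            break
        peak = int(np.argmax(wsig))
        if bg > 0 and kymo.data[t, peak] < config.signal_factor * bg:
            break
        sel = np.abs(cols - peak) <= cent_px
        wts = np.where(sel, sig, 0.0)
        pos_um = float((cols * wts).sum() / wts.sum()) * px
        frames.append(t)
        positions.append(pos_um)
        prev = pos_um
    if not frames:
        raise ValueError("no patch signal above background in frame 0")
    return Track(
        frames=np.array(frames),
        arclen_um=np.array(positions),
        frame_interval_s=movie.frame_interval_s,
        pixel_size_um=px,
        neurite_id=getattr(path, "neurite_id", 0),
    )


def _count_peaks(signal: np.ndarray, config: FlowConfig, px: float) -> int:
    """Well-separated local maxima above half the global peak."""
    sm = ndimage.uniform_filter1d(signal, size=5)
    thr = 0.5 * sm.max()
    peaks = [
        i
        for i in range(1, len(sm) - 1)
        if sm[i] >= thr and sm[i] >= sm[i - 1] and sm[i] > sm[i + 1]
    ]
    if not peaks:
        return 1 if sm.max() > 0 else 0
    merged = [peaks[0]]
    min_sep = 2 * config.search_halfwidth_um / px
    for p in peaks[1:]:
        if p - merged[-1] > min_sep:
            merged.append(p)
    return len(merged)


def speed_from_track(
    track: Track,
    config: FlowConfig | None = None,
    method: str = "net",
    soma_point: np.ndarray | None = None,
) -> FlowMeasurement:
    """Speed and direction of one track.

    ``speed = |net displacement| / duration`` (the kymograph width/height
    rule); ``method="summed"`` uses the summed point-to-point path length
    instead. Works on arc-length tracks or raw 2D/3D point lists (for the
    latter, direction needs ``soma_point``). Tracks no longer than the
    minimum duration are rejected.
    """
    if config is None:
        config = FlowConfig()
    dur = track.duration_min
    if dur <= config.min_track_min:
        raise ValueError(
            f"track duration {dur:.2f} min <= minimum {config.min_track_min} min"
        )
    if track.arclen_um is not None:
        s = track.arclen_um
        net = s[-1] - s[0]
        dist = float(np.abs(np.diff(s)).sum()) if method == "summed" else abs(net)
        signed = net
    else:
        pts = track.points
        net_vec = pts[-1] - pts[0]
        dist = (
            float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            if method == "summed"
            else float(np.linalg.norm(net_vec))
        )
        if soma_point is not None:
            d0 = float(np.linalg.norm(pts[0] - soma_point))
            d1 = float(np.linalg.norm(pts[-1] - soma_point))
            signed = d1 - d0
        else:
            signed = dist  # direction unknown; report as anterograde-signed
    if abs(signed) <= 1e-9 and dist <= 1e-9:
        direction, speed = "immobile", 0.0
    else:
        direction = "retrograde" if signed < 0 else "anterograde"
        speed = dist / dur
    return FlowMeasurement(
        neurite_id=track.neurite_id,
        speed_um_min=speed,
        direction=direction,
        duration_min=dur,
        method="patch",
    )


def patch_synchrony(tracks: list[Track]) -> float:
    """Relative distance difference of co-moving patches in one neurite:
    (furthest traveled - least traveled) / least traveled. NaN when the
    least-traveled distance is zero."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    dists = []
    for tr in tracks:
        s = tr.arclen_um
        if s is None:
            raise ValueError("synchrony needs arc-length tracks")
        dists.append(abs(float(s[-1] - s[0])))
    dmin, dmax = min(dists), max(dists)
    if dmin == 0:
        return float("nan")
    return (dmax - dmin) / dmin


# ---------------------------------------------------------------------------
# CAMSAP3 kymograph traces
# ---------------------------------------------------------------------------

def extract_camsap_traces(
    kymo: Kymograph,
    threshold: float | None = None,
    max_step_px: float = 6.0,
    min_len: int = 3,
) -> list[KymoTrace]:
    """Link thresholded puncta through time by nearest position.

    Per row, connected runs of above-threshold columns become detections
    (intensity-weighted centroids); detections are linked frame-to-frame to
    the nearest open trace within ``max_step_px``. Traces shorter than
    ``min_len`` frames are dropped.
    """
    data = kymo.data
    if threshold is None:
        from skimage import filters

        threshold = float(filters.threshold_otsu(data))
    open_traces: list[dict] = []
    done: list[dict] = []
    for t in range(kymo.n_frames):
        row = data[t]
        mask = row >= threshold
        detections = []
        lbl, nlab = ndimage.label(mask)
        for k in range(1, nlab + 1):
            idx = np.flatnonzero(lbl == k)
            w = row[idx]
            detections.append(float((idx * w).sum() / w.sum()))
        # greedy nearest matching
        unmatched = list(range(len(detections)))
        for tr in list(open_traces):
            if not unmatched:
                break
            dists = [abs(detections[i] - tr["pos"][-1]) for i in unmatched]
            j = int(np.argmin(dists))
            if dists[j] <= max_step_px:
                i = unmatched.pop(j)
                tr["frames"].append(t)
                tr["pos"].append(detections[i])
        for tr in list(open_traces):
            if t - tr["frames"][-1] > 1:
                open_traces.remove(tr)
                done.append(tr)
        for i in unmatched:
            open_traces.append({"frames": [t], "pos": [detections[i]]})
    done.extend(open_traces)
    return [
        KymoTrace(tr["frames"], tr["pos"]) for tr in done if len(tr["frames"]) >= min_len
    ]


def camsap_flow_series(
    traces: list[KymoTrace],
    pixel_size_um: float,
    frame_interval_s: float,
    n_frames: int,
) -> np.ndarray:
    """Per-frame MT-RF speed: the median slope of retrograde traces
    covering each frame; anterograde traces are discarded; frames covered
    by no trace are missing (NaN)."""
    speeds = np.full(n_frames, np.nan)
    per_frame: list[list[float]] = [[] for _ in range(n_frames)]
    for tr in traces:
        v = tr.speed_um_min(pixel_size_um, frame_interval_s)
        if v <= 0:
            continue  # only retrogradely moving signals are considered
        for f in range(int(tr.frames[0]), int(tr.frames[-1]) + 1):
            if 0 <= f < n_frames:
                per_frame[f].append(v)
    for f in range(n_frames):
        if per_frame[f]:
            speeds[f] = float(np.median(per_frame[f]))
    return speeds


# ---------------------------------------------------------------------------
# slowdown detection and polarization stage
# ---------------------------------------------------------------------------

def _rolling_mean_centered(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean, window truncated at the series ends, NaN-aware."""
    n = len(x)
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def detect_slowdown(
    flows: dict[int, np.ndarray],
    axon_id: int,
    config: FlowConfig | None = None,
    frame_interval_s: float = 60.0,
) -> SlowdownResult:
    """Detect the axon-specific MT-RF slowdown.

    Each per-neurite flow series is smoothed with a centered rolling mean
    of ``smooth_window_min``; a time point qualifies when the smoothed axon
    flow is at most ``slowdown_ratio`` times the minimum (or mean, per
    config) of the other neurites. The slowdown is detected when some
    window of ``qualifying_duration_min`` has at least
    ``qualifying_fraction`` qualifying points; the onset is the start of
    the earliest such window. Series spanning less than the qualifying
    duration are not evaluable (distinct from "not detected").
    """
    if config is None:
        config = FlowConfig()
    if axon_id not in flows or len(flows) < 2:
        raise ValueError("need the axon and at least one other neurite")
    dt_min = frame_interval_s / 60.0
    n = len(next(iter(flows.values())))
    if any(len(v) != n for v in flows.values()):
        raise ValueError("flow series must share a common time base")
    span_min = (n - 1) * dt_min
    if span_min < config.qualifying_duration_min:
        return SlowdownResult(False, None, axon_id, evaluable=False)

    w = max(1, int(round(config.smooth_window_min / dt_min)))
    smoothed = {k: _rolling_mean_centered(np.asarray(v, float), w) for k, v in flows.items()}
    others = np.vstack([v for k, v in smoothed.items() if k != axon_id])
    if config.compare_others == "mean":
        ref = np.nanmean(others, axis=0)
    else:
        ref = np.nanmin(others, axis=0)
    axon = smoothed[axon_id]
    qualifying = np.zeros(n, dtype=bool)
    ok = np.isfinite(axon) & np.isfinite(ref)
    qualifying[ok] = axon[ok] <= config.slowdown_ratio * ref[ok]

    win = max(1, int(round(config.qualifying_duration_min / dt_min)))
    for start in range(0, n - win + 1):
        if qualifying[start : start + win].mean() >= config.qualifying_fraction:
            return SlowdownResult(True, start * dt_min, axon_id)
    return SlowdownResult(False, None, axon_id)


def classify_axon(lengths_um: list[float] | np.ndarray) -> str:
    """Polarization stage from neurite lengths.

    ``with_axon``: longest >= 50 um and >= 10 um longer than the second
    longest. ``no_axon``: longest < 50 um and (shorter than 30 um or less
    than 5 um longer than the second longest). Everything else (>= 30 um
    and >= 5 um longer, but not axon-grade) is ``transition``.
    """
    lengths = np.sort(np.asarray(lengths_um, dtype=float))[::-1]
    if len(lengths) < 2:
        raise ValueError("need at least two neurites")
    longest, second = lengths[0], lengths[1]
    if longest >= 50.0 and longest - second >= 10.0:
        return "with_axon"
    if longest < 50.0 and (longest < 30.0 or longest - second < 5.0):
        return "no_axon"
    return "transition"


# ---------------------------------------------------------------------------
# patch spread and mass partition
# ---------------------------------------------------------------------------

def neurite_background(
    kymo: Kymograph, previous_backgrounds: tuple[float, ...] = ()
) -> float:
    """Neurite background: the lowest value among the first five columns in
    the first and the four last rows, floored at the running maximum of
    backgrounds from previous photoconversion intervals (the amount of
    converted tubulin only ever increases)."""
    data = kymo.data
    rows = [0] + list(range(max(0, kymo.n_frames - 4), kymo.n_frames))
    cells = data[np.unique(rows)][:, : min(5, kymo.n_positions)]
    value = float(cells.min())
    if previous_backgrounds:
        value = max(value, float(max(previous_backgrounds)))
    return value


def _start_column(sub: np.ndarray, start_px: int | None) -> int:
    if start_px is not None:
        return int(start_px)
    sm = ndimage.uniform_filter1d(sub[0], size=5)
    return int(np.argmax(sm))


def _analyzed_rows(
    data: np.ndarray, background: float, factor: float
) -> np.ndarray:
    """Rows up to one before the first row whose peak is below
    ``factor * background``."""
    peaks = data.max(axis=1)
    limit = factor * background
    below = np.flatnonzero(peaks < limit)
    stop = below[0] if len(below) else data.shape[0]
    return np.arange(stop)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def patch_spread(
    kymo: Kymograph,
    start_px: int | None = None,
    config: FlowConfig | None = None,
    background: float | None = None,
) -> SpreadResult:
    """Spread of a labeled patch and the speeds of its edges.

    Per analyzed row of the background-subtracted kymograph, the
    lower-valued of the two current edge pixels is removed until at least
    ``spread_trim_fraction`` of the row's summed intensity is gone (ties
    remove the pixel farther from the start, or both when equidistant);
    the spread is the distance between the surviving extremes. Edge speeds
    are the displacement of the surviving extreme pixels beyond 1.1 um
    retrograde / anterograde of the start point, over the time up to the
    last analyzed row (rows are analyzed while the peak stays at least
    ``signal_factor`` times the background).
    """
    if config is None:
        config = FlowConfig()
    if background is None:
        background = neurite_background(kymo)
    sub = np.clip(kymo.data - background, 0.0, None)
    rows = _analyzed_rows(kymo.data, background, config.signal_factor)
    if len(rows) == 0:
        raise ValueError("first row already below the signal threshold")
    start = _start_column(sub, start_px)
    px = kymo.pixel_size_um
    half_px = _round_half_up(config.stationary_half_um / px)

    spreads, lefts, rights = [], [], []
    for t in rows:
        row = sub[t].copy()
        nz = np.flatnonzero(row > 0)
        if len(nz) == 0:
            spreads.append(0.0)
            lefts.append(start)
            rights.append(start)
            continue
        left, right = int(nz[0]), int(nz[-1])
        total = row.sum()
        removed = 0.0
        while removed < config.spread_trim_fraction * total and left < right:
            vl, vr = row[left], row[right]
            if vl < vr:
                pick = ("l",)
            elif vr < vl:
                pick = ("r",)
            else:  # tie: remove the farther edge; both when equidistant
                dl, dr = abs(start - left), abs(right - start)
                pick = ("l", "r") if dl == dr else (("l",) if dl > dr else ("r",))
            for p in pick:
                if p == "l":
                    removed += row[left]
                    row[left] = 0.0
                    while left < right and row[left] == 0:
                        left += 1
                else:
                    removed += row[right]
                    row[right] = 0.0
                    while right > left and row[right] == 0:
                        right -= 1
        spreads.append((right - left) * px)
        lefts.append(left)
        rights.append(right)

    t_last = int(rows[-1])
    dt_min = kymo.frame_interval_min
    if t_last == 0:
        retro_v = antero_v = float("nan")
    else:
        retro_mark = start - half_px
        antero_mark = start + half_px
        retro_dist = max(0, retro_mark - lefts[-1]) * px
        antero_dist = max(0, rights[-1] - antero_mark) * px
        retro_v = retro_dist / (t_last * dt_min)
        antero_v = antero_dist / (t_last * dt_min)
    return SpreadResult(
        rows=rows,
        spread_um=np.array(spreads),
        retro_speed_um_min=retro_v,
        antero_speed_um_min=antero_v,
    )


def mass_distribution(
    kymo: Kymograph,
    start_px: int | None = None,
    config: FlowConfig | None = None,
    latB_mode: bool = False,
    background: float | None = None,
    previous_backgrounds: tuple[float, ...] = (),
) -> tuple[float, float, float]:
    """Partition of labeled microtubule mass around the labeling site.

    After neurite-background subtraction, the summed intensity (microtubule
    mass) more than 1.1 um retrograde of the start point, within +-1.1 um,
    and more than 1.1 um anterograde is divided by the whole-neurite sum
    per row; the per-row fractions are averaged over the analyzed rows
    (rows up to one before the first whose peak falls below 1.8-fold — or
    1.3-fold with LatB — of the background). Returns
    ``(retrograde, stationary, anterograde)`` fractions summing to 1.
    """
    if config is None:
        config = FlowConfig()
    if background is None:
        background = neurite_background(kymo, previous_backgrounds)
    sub = np.clip(kymo.data - background, 0.0, None)
    factor = config.row_stop_factor_latb if latB_mode else config.row_stop_factor
    rows = _analyzed_rows(kymo.data, background, factor)
    if len(rows) == 0:
        raise ValueError("first row already below the signal threshold")
    start = _start_column(sub, start_px)
    px = kymo.pixel_size_um
    half = _round_half_up(config.stationary_half_um / px)

    fracs = []
    for t in rows:
        row = sub[t]
        total = row.sum()
        if total <= 0:
            continue
        retro = row[: max(0, start - half)].sum()
        stat = row[max(0, start - half) : start + half + 1].sum()
        antero = row[start + half + 1 :].sum()
        fracs.append((retro / total, stat / total, antero / total))
    if not fracs:
        raise ValueError("zero total mass in all analyzed rows")
    mean = np.mean(np.asarray(fracs), axis=0)
    return float(mean[0]), float(mean[1]), float(mean[2])
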