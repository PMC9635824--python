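"""Kymograph construction and kymograph-derived measurements.

A kymograph is sampled along a traced path with the soma at column 0
(soma-left orientation, so retrograde movement slopes leftward over time);
each entry is the maximum intensity across a sampling line perpendicular to
the local path direction, which keeps dim moving puncta visible even when
the path is slightly off their center.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import filters

from .core import Kymograph, MovieStack

__all__ = [
    "sample_kymograph",
    "neurite_length_series",
    "proximal_distal_density",
    "soma_fraction",
]


def _resample_path(points: np.ndarray, step_px: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing (pixels)."""
    pts = np.asarray(points, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    n = max(2, int(np.floor(total / step_px)) + 1)
    si = np.arange(n) * step_px
    return np.column_stack(
        [np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])]
    )


def _tangents(pts: np.ndarray) -> np.ndarray:
    """Unit tangents from a 5-point central difference (clamped at ends)."""
    n = len(pts)
    idx = np.arange(n)
    lo = np.clip(idx - 2, 0, n - 1)
    hi = np.clip(idx + 2, 0, n - 1)
    t = pts[hi] - pts[lo]
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return t / norm


def sample_kymograph(movie: MovieStack, path, width_px: int = 11, channel=0) -> Kymograph:
    """Kymograph of one channel along a path.

    ``path`` is any object with ``points`` (ordered soma-to-tip, (N, 2)
    ``(y, x)`` pixels) and ``pixel_size_um``. The path is resampled to 1
    pixel of arc length per column; each value is the maximum intensity
    over ``width_px`` nearest-pixel samples perpendicular to the local path
    tangent. Points sampling outside the frame are clipped with a warning.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")
    frames = movie.channel(channel)
    h, w = frames.shape[1:]
    pts = _resample_path(path.points, 1.0)
    tang = _tangents(pts)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px) - width_px // 2
    # (n_points, width, 2) sampling coordinates
    coords = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    iy = np.rint(coords[..., 0]).astype(int)
    ix = np.rint(coords[..., 1]).astype(int)
    if (iy < 0).any() or (iy >= h).any() or (ix < 0).any() or (ix >= w).any():
        warnings.warn("path sampling exits the frame; coordinates clipped")
    iy = np.clip(iy, 0, h - 1)
    ix = np.clip(ix, 0, w - 1)
    data = frames[:, iy, ix].max(axis=2)  # (T, n_points)
    return Kymograph(
        data,
        pixel_size_um=path.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
        width_px=width_px,
        path_id=getattr(path, "neurite_id", 0),
    )


def neurite_length_series(
    kymo: Kymograph,
    threshold: float | None = None,
    smooth_mode: str = "isotropic2",
    dilate_before_fill: bool = False,
) -> np.ndarray:
    """Per-frame neurite length (um) from a thresholded kymograph.

    The kymograph is median-smoothed (``isotropic2``: 2x2 footprint;
    ``rowwise5``: 1x5 across position only, which avoids smoothing over
    time), thresholded (a manually chosen value always wins; Otsu is the
    fallback), the first and last time points are forced into the
    thresholded set so holes can be filled, holes are filled (optionally
    after one binary dilation), and the length of frame ``t`` is the
    distance from the soma to one pixel before the first unthresholded
    pixel closest to the soma.
    """
    data = kymo.data
    if smooth_mode == "isotropic2":
        sm = ndimage.median_filter(data, size=2)
    elif smooth_mode == "rowwise5":
        sm = ndimage.median_filter(data, size=(1, 5))
    else:
        raise ValueError(f"unknown smooth_mode {smooth_mode!r}")
    if threshold is None:
        threshold = float(filters.threshold_otsu(sm))
    mask = sm >= threshold
    mask[0, :] = True
    mask[-1, :] = True
    if dilate_before_fill:
        mask = ndimage.binary_dilation(mask, structure=np.ones((2, 2)))
    mask = ndimage.binary_fill_holes(mask)
    lengths = np.zeros(kymo.n_frames)
    for t in range(kymo.n_frames):
        row = mask[t]
        if not row[0]:
            lengths[t] = 0.0
            continue
        gaps = np.flatnonzero(~row)
        last_px = (gaps[0] - 1) if len(gaps) else (len(row) - 1)
        lengths[t] = last_px * kymo.pixel_size_um
    return lengths


def proximal_distal_density(
    kymo: Kymograph,
    lengths_um: np.ndarray,
    threshold: float | None = None,
    norm_window_min: float = 22.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean thresholded intensity in the first 5 um (proximal) and within
    5-10 um from the neurite tip (distal), per frame, each normalized to
    its own mean over the first ``norm_window_min`` minutes.

    Frames whose neurite is shorter than 10 um get a missing (NaN) distal
    value.
    """
    data = kymo.data
    if threshold is None:
        threshold = float(filters.threshold_otsu(data))
    px = kymo.pixel_size_um
    n = kymo.n_frames
    prox = np.full(n, np.nan)
    dist = np.full(n, np.nan)
    for t in range(n):
        row = data[t]
        sel = row >= threshold
        p_hi = int(np.floor(5.0 / px))
        zone = sel[: p_hi + 1]
        if zone.any():
            prox[t] = row[: p_hi + 1][zone].mean()
        length = lengths_um[t]
        if length >= 10.0:
            d_lo = int(np.ceil((length - 10.0) / px))
            d_hi = int(np.floor((length - 5.0) / px))
            zone = sel[d_lo : d_hi + 1]
            if zone.any():
                dist[t] = row[d_lo : d_hi + 1][zone].mean()
    n_norm = max(1, int(round(norm_window_min * 60.0 / kymo.frame_interval_s)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p0 = np.nanmean(prox[:n_norm])
        d0 = np.nanmean(dist[:n_norm])
    if np.isfinite(p0) and p0 != 0:
        prox = prox / p0
    if np.isfinite(d0) and d0 != 0:
        dist = dist / d0
    return prox, dist


def soma_fraction(
    movie: MovieStack,
    soma_region: np.ndarray,
    cell_region: np.ndarray,
    threshold: float,
    background: float | None = None,
    channel=0,
) -> np.ndarray:
    """Per-frame fraction of total fluorescence located in the soma.

    Total fluorescence of a region is the background-subtracted intensity
    summed over its thresholded pixels (equivalently: background-subtracted
    mean times thresholded-pixel count). Frames with zero total cell
    fluorescence yield NaN.
    """
    soma_region = np.asarray(soma_region, dtype=bool)
    cell_region = np.asarray(cell_region, dtype=bool)
    if (soma_region & ~cell_region).any():
        raise ValueError("soma_region must be contained in cell_region")
    frames = movie.channel(channel)
    out = np.full(movie.n_frames, np.nan)
    for t in range(movie.n_frames):
        frame = frames[t].astype(float)
        mask = frame >= threshold
        if background is None:
            outside = frame[~mask]
            bg = float(outside.mean()) if outside.size else 0.0
        else:
            bg = background
        sub = frame - bg
        total_cell = sub[cell_region & mask].sum()
        if total_cell > 0:
            out[t] = float(np.clip(sub[soma_region & mask].sum() / total_cell, 0.0, 1.0))
    return out
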