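"""Translation registration of low-intensity time-lapse movies.

Frames are registered by maximizing the Pearson correlation with a
reference frame under cyclic (rolled) integer-pixel translations: a coarse
stage expands a ring of candidate directions until the best direction is
stable, then a per-dimension walk refines the shift. The best shift of one
frame seeds the next, and the reference frame is replaced adaptively when
the correlation drops, which typically signals a morphology change of the
cell. Hot pixels are capped at a few standard deviations above the mean
beforehand so that a handful of bright pixels cannot dominate the
correlation.

Because frames are shifted by cyclic rolling during the search, the
correlation is always computed over the full frame; wrapped margins are
zero-filled in the registered output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MovieStack

__all__ = [
    "RegistrationConfig",
    "ShiftSeries",
    "cap_intensities",
    "find_shift",
    "register_movie",
    "apply_shifts",
]

# 8-neighbor directions in fixed row-major scan order; correlation ties are
# broken by this order.
_DIRECTIONS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass
class RegistrationConfig:
    k_sd: float = 6.0  # cap at mean + k_sd * SD
    per_pixel_cap: bool = False
    lookahead_px: int = 2  # refinement keeps probing this far past the best
    direction_streak: int = 5  # coarse stage stops after this many repeats
    ref_switch_sd: float = 2.0
    ref_switch_two_sided: bool = False  # default: only a drop triggers a switch
    ref_switch_min_accepted: int = 3
    slice_mode: bool = False  # additionally renew the reference every 3 frames
    slice_ref_every: int = 3
    channel: int | str = 0  # channel used to estimate shifts
    max_radius: int | None = None


@dataclass
class ShiftSeries:
    """Per-frame integer shift, correlation and reference-frame index."""

    shifts: np.ndarray  # (T, 2) int, (dy, dx) applied to each frame
    correlations: np.ndarray  # (T,)
    reference_frame: np.ndarray  # (T,) int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.reference_frame = np.asarray(self.reference_frame, dtype=int)
        if not np.all(self.shifts[0] == 0):
            raise ValueError("shift of the first frame must be zero")

    @property
    def n_frames(self) -> int:
        return len(self.shifts)


def cap_intensities(
    movie: MovieStack, k_sd: float = 6.0, per_pixel: bool = False
) -> MovieStack:
    """Clip each channel above ``mean + k_sd * SD``.

    Statistics are computed globally over all frames and pixels of the
    channel by default; with ``per_pixel=True`` they are computed per pixel
    over time instead. Values below the cap are unchanged.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    if movie.data.size == 0 or movie.n_frames == 0:
        raise ValueError("cannot cap an empty movie")
    out = np.empty_like(movie.data, dtype=float)
    for c in range(movie.n_channels):
        frames = movie.data[c].astype(float)
        if per_pixel:
            cap = frames.mean(axis=0) + k_sd * frames.std(axis=0)
            out[c] = np.minimum(frames, cap[None])
        else:
            cap = frames.mean() + k_sd * frames.std()
            out[c] = np.minimum(frames, cap)
    return MovieStack(
        out, movie.pixel_size_um, movie.frame_interval_s, movie.channel_names
    )


def _prep(frame: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean-subtracted frame and its norm (invariant under cyclic rolls)."""
    f0 = frame.astype(float) - frame.mean()
    return f0, float(np.sqrt((f0 * f0).sum()))


def find_shift(
    reference: np.ndarray,
    frame: np.ndarray,
    start_shift: tuple[int, int] = (0, 0),
    lookahead_px: int = 2,
    direction_streak: int = 5,
    max_radius: int | None = None,
) -> tuple[tuple[int, int], float]:
    """Best integer translation of ``frame`` onto ``reference``.

    Coarse stage: starting from ``start_shift``, the Pearson correlation is
    evaluated at the 8 one-pixel neighbor directions at successively
    increasing radius; the search stops once the best direction has repeated
    ``direction_streak`` consecutive times. Refinement: per dimension, the
    shift steps one pixel at a time in the improving direction, probing up
    to ``lookahead_px`` past the best value found, repeated over dimensions
    until no dimension improves.

    Returns the shift (to be applied to ``frame`` with ``np.roll``) and its
    Pearson correlation over the full (cyclically rolled) frames. Degenerate
    zero-variance frames return ``start_shift`` with correlation ``nan``.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if reference.shape != frame.shape:
        raise ValueError("reference and frame must have the same shape")
    ref0, ref_norm = _prep(reference)
    frm0, frm_norm = _prep(frame)
    if ref_norm == 0 or frm_norm == 0:
        return tuple(int(v) for v in start_shift), float("nan")
    denom = ref_norm * frm_norm
    if max_radius is None:
        max_radius = max(1, min(frame.shape) // 3)

    cache: dict[tuple[int, int], float] = {}

    def corr(shift: tuple[int, int]) -> float:
        shift = (int(shift[0]), int(shift[1]))
        if shift not in cache:
            rolled = np.roll(frm0, shift, axis=(0, 1))
            cache[shift] = float((ref0 * rolled).sum() / denom)
        return cache[shift]

    start = (int(start_shift[0]), int(start_shift[1]))
    best_shift, best_corr = start, corr(start)

    # coarse stage: expanding ring of 8 directions
    prev_dir, streak = None, 0
    for radius in range(1, max_radius + 1):
        ring_best_dir, ring_best_corr = None, -np.inf
        for d in _DIRECTIONS:
            c = corr((start[0] + radius * d[0], start[1] + radius * d[1]))
            if c > ring_best_corr:
                ring_best_corr, ring_best_dir = c, d
        if ring_best_corr > best_corr:
            best_corr = ring_best_corr
            best_shift = (
                start[0] + radius * ring_best_dir[0],
                start[1] + radius * ring_best_dir[1],
            )
        if ring_best_dir == prev_dir:
            streak += 1
        else:
            prev_dir, streak = ring_best_dir, 1
        if streak >= direction_streak:
            break

    # refinement: per-dimension one-pixel walk with lookahead
    improved = True
    while improved:
        improved = False
        for dim in (0, 1):
            for sign in (1, -1):
                step = [0, 0]
                step[dim] = sign
                if corr((best_shift[0] + step[0], best_shift[1] + step[1])) <= best_corr:
                    continue
                # walk in this direction until no improvement for lookahead_px
                k, k_best = 0, 0
                local_best_shift, local_best_corr = best_shift, best_corr
                while k - k_best < max(1, lookahead_px):
                    k += 1
                    cand = (best_shift[0] + k * step[0], best_shift[1] + k * step[1])
                    c = corr(cand)
                    if c > local_best_corr:
                        local_best_shift, local_best_corr, k_best = cand, c, k
                if local_best_corr > best_corr:
                    best_shift, best_corr = local_best_shift, local_best_corr
                    improved = True
    return best_shift, best_corr


def _zero_fill(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Zero the margins that wrapped around during the cyclic roll."""
    dy, dx = int(shift[0]), int(shift[1])
    out = frame.copy()
    if dy > 0:
        out[:dy, :] = 0
    elif dy < 0:
        out[dy:, :] = 0
    if dx > 0:
        out[:, :dx] = 0
    elif dx < 0:
        out[:, dx:] = 0
    return out


def apply_shifts(movie: MovieStack, series: ShiftSeries) -> MovieStack:
    """Roll every channel of the movie by the per-frame shifts and zero-fill
    the wrapped margins."""
    if series.n_frames != movie.n_frames:
        raise ValueError("shift series length does not match movie")
    out = np.empty_like(movie.data, dtype=float)
    for c in range(movie.n_channels):
        for t in range(movie.n_frames):
            shift = tuple(series.shifts[t])
            rolled = np.roll(movie.data[c, t].astype(float), shift, axis=(0, 1))
            out[c, t] = _zero_fill(rolled, shift)
    return MovieStack(
        out, movie.pixel_size_um, movie.frame_interval_s, movie.channel_names
    )


def register_movie(
    movie: MovieStack, config: RegistrationConfig | None = None
) -> tuple[MovieStack, ShiftSeries]:
    """Register a movie by per-frame translation.

    Shifts are estimated on the capped ``config.channel``; the best shift of
    frame ``t`` seeds the search for frame ``t + 1``. The reference frame is
    replaced by the current (registered) frame when its correlation falls at
    least ``ref_switch_sd`` standard deviations below the running mean of
    accepted correlations (running statistics start after
    ``ref_switch_min_accepted`` frames), and additionally every
    ``slice_ref_every`` frames in slice mode. The returned movie contains
    the original (uncapped) intensities of all channels, shifted, with
    wrapped margins zero-filled.
    """
    if config is None:
        config = RegistrationConfig()
    n = movie.n_frames
    capped = cap_intensities(movie, config.k_sd, config.per_pixel_cap)
    work = capped.channel(config.channel)

    shifts = np.zeros((n, 2), dtype=int)
    corrs = np.full(n, 1.0)
    ref_idx = np.zeros(n, dtype=int)
    if n > 1:
        ref = work[0]
        current_ref = 0
        last_ref_t = 0
        accepted: list[float] = []
        for t in range(1, n):
            shift, corr = find_shift(
                ref,
                work[t],
                start_shift=tuple(shifts[t - 1]),
                lookahead_px=config.lookahead_px,
                direction_streak=config.direction_streak,
                max_radius=config.max_radius,
            )
            shifts[t] = shift
            corrs[t] = corr
            ref_idx[t] = current_ref

            switch = False
            if len(accepted) >= config.ref_switch_min_accepted:
                m = float(np.mean(accepted))
                s = float(np.std(accepted))
                if s > 0 and np.isfinite(corr):
                    dev = abs(corr - m) if config.ref_switch_two_sided else (m - corr)
                    if dev >= config.ref_switch_sd * s:
                        switch = True
            if config.slice_mode and (t - last_ref_t) >= config.slice_ref_every:
                switch = True
            if np.isfinite(corr):
                accepted.append(corr)
            if switch:
                ref = np.roll(work[t], tuple(shifts[t]), axis=(0, 1))
                current_ref = t
                last_ref_t = t
                accepted = []

    series = ShiftSeries(shifts=shifts, correlations=corrs, reference_frame=ref_idx)
    return apply_shifts(movie, series), series
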