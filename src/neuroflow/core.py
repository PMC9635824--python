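"""Shared containers for movies, kymographs and tracks.

Conventions used throughout the package:

- Pixel coordinates are 0-based ``(row, column)`` = ``(y, x)``.
- Movies are arrays of shape ``(C, T, H, W)`` (channel, time, rows, cols).
- Kymographs have rows = time frames and columns = arc-length bins with the
  soma at column 0, so retrograde movement appears as a leftward slope.
- Retrograde speeds are reported as positive numbers; the direction is
  carried by a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MovieStack", "Kymograph", "Track", "NeuritePath"]


@dataclass
class MovieStack:
    """A time-lapse fluorescence movie.

    ``data`` is ``(C, T, H, W)``; single-channel movies use ``C == 1``.
    ``pixel_size_um`` is the lateral sampling in micrometres per pixel and
    ``frame_interval_s`` the time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # (T, H, W) -> single channel
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("movie data must be (T,H,W) or (C,T,H,W)")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return the ``(T, H, W)`` frames of one channel."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.data[idx]

    def single(self, name_or_index: str | int) -> "MovieStack":
        """A single-channel view (copy of metadata, shared frame data)."""
        name = (
            name_or_index
            if isinstance(name_or_index, str)
            else self.channel_names[name_or_index]
        )
        return MovieStack(
            self.channel(name_or_index)[None],
            self.pixel_size_um,
            self.frame_interval_s,
            (name,),
        )


@dataclass
class NeuritePath:
    """An ordered path of points from the soma outward.

    ``points`` is ``(N, 2)`` float ``(y, x)`` pixel coordinates;
    ``arclen_um`` is the cumulative arc length from the first (soma-side)
    point in micrometres.
    """

    points: np.ndarray
    pixel_size_um: float
    neurite_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("path points must be (N, 2)")

    @property
    def arclen_um(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)]) * self.pixel_size_um

    @property
    def length_um(self) -> float:
        return float(self.arclen_um[-1])

    def point_at_arclen(self, s_um: float) -> np.ndarray:
        """Linear interpolation of the (y, x) position at arc length ``s_um``."""
        s = self.arclen_um
        y = np.interp(s_um, s, self.points[:, 0])
        x = np.interp(s_um, s, self.points[:, 1])
        return np.array([y, x])


@dataclass
class Kymograph:
    """Distance-versus-time matrix sampled along a neurite path.

    Rows are time frames, columns are arc-length bins (1 pixel of arc
    length per column) with the soma at column 0.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    width_px: int = 11
    path_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (frames x positions)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[1]

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0


@dataclass
class Track:
    """A tracked entity (patch, punctum or comet) over time.

    ``frames`` are frame indices; ``points`` optional ``(N, D)`` spatial
    pixel coordinates; ``arclen_um`` optional per-frame arc-length position
    along a neurite path (soma = 0).
    """

    frames: np.ndarray
    points: np.ndarray | None = None
    arclen_um: np.ndarray | None = None
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.22
    entity_id: int = 0
    neurite_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float)
        if self.arclen_um is not None:
            self.arclen_um = np.asarray(self.arclen_um, dtype=float)
        if self.points is None and self.arclen_um is None:
            raise ValueError("track needs points or arc-length positions")

    @property
    def n_timepoints(self) -> int:
        return len(self.frames)

    @property
    def duration_min(self) -> float:
        return (self.frames[-1] - self.frames[0]) * self.frame_interval_s / 60.0

    def reversed(self) -> "Track":
        """Time-reversed copy: the trajectory runs backwards while frame
        indices still ascend (used for antisymmetry checks)."""
        return Track(
            frames=self.frames[0] + (self.frames[-1] - self.frames)[::-1],
            points=None if self.points is None else self.points[::-1].copy(),
            arclen_um=None if self.arclen_um is None else self.arclen_um[::-1].copy(),
            frame_interval_s=self.frame_interval_s,
            pixel_size_um=self.pixel_size_um,
            entity_id=self.entity_id,
            neurite_id=self.neurite_id,
            meta=dict(self.meta),
        )
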