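"""Readers and writers for the package's on-disk formats.

Movies are multi-page TIFFs with channel-interleaved pages (frame-major:
page ``t * C + c`` holds frame ``t`` of channel ``c``); kymographs are
single-page TIFFs with a JSON sidecar carrying pixel size, frame interval
and path id; tracks, branches and shifts are plain CSV with documented
headers. Pixel coordinates in all tables are 0-based ``(y, x)`` row/column
indices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Kymograph, MovieStack, Track
from .registration import ShiftSeries

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_kymograph",
    "read_kymograph",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_branches_csv",
    "write_shifts_csv",
    "read_shifts_csv",
    "write_ground_truth_json",
]


def write_movie_tiff(movie: MovieStack, path: str | Path) -> None:
    """Channel-interleaved multi-page TIFF (page = t * C + c)."""
    c, t, h, w = movie.data.shape
    pages = movie.data.transpose(1, 0, 2, 3).reshape(t * c, h, w).astype(np.float32)
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "n_channels": c,
        "channel_names": list(movie.channel_names),
    }
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def read_movie_tiff(
    path: str | Path,
    n_channels: int | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> MovieStack:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        pass
    c = n_channels or int(meta.get("n_channels", 1))
    px = pixel_size_um or float(meta.get("pixel_size_um", 1.0))
    dt = frame_interval_s or float(meta.get("frame_interval_s", 1.0))
    names = tuple(meta.get("channel_names", ()))
    if pages.ndim == 2:
        pages = pages[None]
    t = pages.shape[0] // c
    data = pages[: t * c].reshape(t, c, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return MovieStack(data, px, dt, names)


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), kymo.data.astype(np.float32))
    sidecar = {
        "pixel_size_um": kymo.pixel_size_um,
        "frame_interval_s": kymo.frame_interval_s,
        "width_px": kymo.width_px,
        "path_id": kymo.path_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    data = tifffile.imread(str(path))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Kymograph(
        data,
        pixel_size_um=sidecar["pixel_size_um"],
        frame_interval_s=sidecar["frame_interval_s"],
        width_px=sidecar.get("width_px", 11),
        path_id=sidecar.get("path_id", 0),
    )


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    """Columns: entity_id, frame, x_px, y_px, arclen_um."""
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append(
                {
                    "entity_id": tr.entity_id,
                    "frame": int(f),
                    "x_px": float(tr.points[i, 1]) if tr.points is not None else np.nan,
                    "y_px": float(tr.points[i, 0]) if tr.points is not None else np.nan,
                    "arclen_um": float(tr.arclen_um[i])
                    if tr.arclen_um is not None
                    else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(
    path: str | Path, pixel_size_um: float = 0.22, frame_interval_s: float = 1.0
) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for eid, grp in df.groupby("entity_id"):
        grp = grp.sort_values("frame")
        pts = grp[["y_px", "x_px"]].to_numpy(dtype=float)
        arclen = grp["arclen_um"].to_numpy(dtype=float) if "arclen_um" in grp else None
        if arclen is not None and np.all(np.isnan(arclen)):
            arclen = None
        tracks.append(
            Track(
                frames=grp["frame"].to_numpy(dtype=int),
                points=None if np.all(np.isnan(pts)) else pts,
                arclen_um=arclen,
                frame_interval_s=frame_interval_s,
                pixel_size_um=pixel_size_um,
                entity_id=int(eid),
            )
        )
    return tracks


def write_branches_csv(branches, path: str | Path) -> None:
    """Columns: frame, neurite_id, branch_id, point_index, y_px, x_px,
    arclen_um, intensity."""
    rows = []
    for b in branches:
        arclen = b.arclen_um
        for i, (y, x) in enumerate(b.points):
            rows.append(
                {
                    "frame": b.frame,
                    "neurite_id": b.neurite_id,
                    "branch_id": b.branch_id,
                    "point_index": i,
                    "y_px": int(y),
                    "x_px": int(x),
                    "arclen_um": float(arclen[i]),
                    "intensity": float(b.intensity[i])
                    if b.intensity is not None
                    else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_shifts_csv(series: ShiftSeries, path: str | Path) -> None:
    """Columns: frame, dy_px, dx_px, correlation, reference_frame."""
    pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "dy_px": series.shifts[:, 0],
            "dx_px": series.shifts[:, 1],
            "correlation": series.correlations,
            "reference_frame": series.reference_frame,
        }
    ).to_csv(path, index=False)


def read_shifts_csv(path: str | Path) -> ShiftSeries:
    df = pd.read_csv(path)
    return ShiftSeries(
        shifts=df[["dy_px", "dx_px"]].to_numpy(dtype=int),
        correlations=df["correlation"].to_numpy(dtype=float),
        reference_frame=df["reference_frame"].to_numpy(dtype=int),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_ground_truth_json(truth, path: str | Path) -> None:
    d = dataclasses.asdict(truth)
    d["paths"] = [
        {"neurite_id": p.neurite_id, "points": p.points, "pixel_size_um": p.pixel_size_um}
        for p in truth.paths
    ]
    Path(path).write_text(json.dumps(d, cls=_NumpyEncoder))
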