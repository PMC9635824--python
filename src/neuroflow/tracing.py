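"""Fully automated neurite tracing from a cytosolic / tubulin channel.

Per frame the stages are: locate the soma (grey opening, Scharr edge
magnitude, Otsu thresholding of the edges, hole filling), find the neuron
threshold (the lowest threshold reproducing the soma size, then raised
until neurite skeleton pixels start being lost), close gaps in the
thresholded image by bridging detached segments back toward the soma under
a direction constraint, and finally decompose the soma-connected skeleton
into branches rooted at the soma with length- and size-based filters.

The tracing works for markers that label the cytosol or neurite shaft; it
is not meant for tip-enriched markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure, morphology

__all__ = [
    "TracingConfig",
    "SomaMask",
    "NeuriteBranch",
    "NoSomaError",
    "extract_soma",
    "find_neuron_threshold",
    "close_gaps",
    "build_branches",
    "trace_frame",
    "filter_overlapping_branches",
]


class NoSomaError(ValueError):
    """Raised when no soma-sized component can be extracted."""


@dataclass
class TracingConfig:
    grey_open_radius_px: int = 10  # must exceed neurite width, stay below soma radius
    min_soma_area_px: int = 50
    soma_area_tol: float = 0.05
    threshold_step_frac: float = 0.01  # of the frame's dynamic range
    skeleton_loss_px: int = 5
    cumulative_skeleton_loss: bool = False
    gap_angle_tol_deg: float = 45.0
    max_gap_px: float = 30.0
    min_branch_points: int = 40
    min_terminal_um: float = 1.0
    overlap_frac: float = 0.7
    intensity_ratio_band: tuple[float, float] = (0.5, 2.0)
    soma_dilate_px: int = 2
    root_max_dist_px: float = 6.0  # skeleton-to-soma gap tolerated at the root

    def __post_init__(self) -> None:
        if not 0 < self.overlap_frac <= 1:
            raise ValueError("overlap_frac must be in (0, 1]")
        if self.soma_area_tol <= 0 or self.threshold_step_frac <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SomaMask:
    mask: np.ndarray
    centroid: tuple[float, float]
    area: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area <= 0:
            raise ValueError("soma area must be > 0")


@dataclass
class NeuriteBranch:
    """Ordered skeleton path from a soma-adjacent origin to a tip."""

    points: np.ndarray  # (N, 2) int (row, col)
    pixel_size_um: float
    neurite_id: int = 0
    branch_id: int = 0
    intensity: np.ndarray | None = None
    frame: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("branch points must be (N, 2)")

    @property
    def arclen_um(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points.astype(float), axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)]) * self.pixel_size_um

    @property
    def length_um(self) -> float:
        return float(self.arclen_um[-1])

    @property
    def n_points(self) -> int:
        return len(self.points)


def extract_soma(frame: np.ndarray, config: TracingConfig | None = None) -> SomaMask:
    """Locate the soma as the largest filled region enclosed by the edge
    magnitude of the grey-opened frame.

    Grey opening with a disk larger than the neurite width removes neurites
    while preserving the soma body; Scharr edges of the result outline the
    soma, the Otsu-thresholded edge map is hole-filled, and a one-pixel
    erosion compensates the finite width of the edge ring.
    """
    if config is None:
        config = TracingConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise NoSomaError("empty frame")
    opened = ndimage.grey_opening(
        frame, footprint=morphology.disk(config.grey_open_radius_px)
    )
    edges = filters.scharr(opened)
    if edges.max() <= 0:
        raise NoSomaError("no soma: frame has no edges")
    thresh = filters.threshold_otsu(edges)
    filled = ndimage.binary_fill_holes(edges > thresh)
    filled = morphology.erosion(filled, morphology.disk(1))
    labels = measure.label(filled, connectivity=2)
    if labels.max() == 0:
        raise NoSomaError("no soma: no filled component")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < config.min_soma_area_px:
        raise NoSomaError(
            f"no soma: largest component area {areas[best - 1]} "
            f"< {config.min_soma_area_px}"
        )
    mask = labels == best
    cy, cx = ndimage.center_of_mass(mask)
    return SomaMask(mask=mask, centroid=(float(cy), float(cx)), area=int(mask.sum()))


def _soma_component_area(
    mask: np.ndarray, soma: SomaMask, config: TracingConfig
) -> int:
    """Size of the soma body extracted at a candidate threshold: the
    component at the soma centroid after binary opening with the same disk
    used for soma extraction (the opening strips neurites so the comparison
    is soma against soma)."""
    opened = morphology.opening(mask, morphology.disk(config.grey_open_radius_px))
    labels = measure.label(opened, connectivity=2)
    r = int(round(soma.centroid[0]))
    c = int(round(soma.centroid[1]))
    r = min(max(r, 0), mask.shape[0] - 1)
    c = min(max(c, 0), mask.shape[1] - 1)
    lab = labels[r, c]
    if lab == 0:
        return 0
    return int((labels == lab).sum())


def find_neuron_threshold(
    frame: np.ndarray, soma: SomaMask, config: TracingConfig | None = None
) -> float:
    """Threshold that keeps the full neuron without eating the neurites.

    Starting from the lowest threshold whose extracted soma size matches the
    edge-derived soma area within tolerance, the threshold is raised in
    steps of ``threshold_step_frac`` of the dynamic range, skeletonizing at
    each step; the function returns the threshold one step before the first
    step at which ``skeleton_loss_px`` or more skeleton pixels are lost
    (per-step by default, cumulative with ``cumulative_skeleton_loss``).
    """
    if config is None:
        config = TracingConfig()
    frame = np.asarray(frame, dtype=float)
    lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        raise NoSomaError("uniform frame: no soma/edge agreement possible")
    step = config.threshold_step_frac * (hi - lo)
    thresholds = np.arange(lo + step, hi, step)

    start_idx = None
    tried = []
    for i, t in enumerate(thresholds):
        area = _soma_component_area(frame > t, soma, config)
        tried.append((t, area))
        if area > 0 and abs(area - soma.area) / soma.area <= config.soma_area_tol:
            start_idx = i
            break
    if start_idx is None:
        areas = ", ".join(f"{t:.3g}->{a}" for t, a in tried[:: max(1, len(tried) // 8)])
        raise NoSomaError(
            f"no threshold reproduces soma area {soma.area} within "
            f"{config.soma_area_tol:.0%} (sampled: {areas})"
        )

    prev_t = float(thresholds[start_idx])
    prev_count = int(morphology.skeletonize(frame > prev_t).sum())
    base_count = prev_count
    for t in thresholds[start_idx + 1 :]:
        count = int(morphology.skeletonize(frame > t).sum())
        lost = (base_count - count) if config.cumulative_skeleton_loss else (prev_count - count)
        if lost >= config.skeleton_loss_px:
            return prev_t
        prev_t, prev_count = float(t), count
    return prev_t


def _component_orientation(points: np.ndarray) -> float:
    """Principal-axis angle of a point set, in radians, undirected."""
    pts = points.astype(float)
    pts = pts - pts.mean(axis=0)
    if len(pts) < 2:
        return 0.0
    cov = pts.T @ pts
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, int(np.argmax(vals))]
    return float(np.arctan2(v[0], v[1]))


def _angle_diff_axis(a: float, b: float) -> float:
    """Unsigned difference of two undirected axis angles, in [0, pi/2]."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def close_gaps(
    binary: np.ndarray, soma: SomaMask, config: TracingConfig | None = None
) -> np.ndarray:
    """Reconnect segments detached from the soma-connected component.

    Each detached component is bridged by a 1-px straight line from its
    soma-closest point to the nearest soma-connected point whose bearing
    lies within ``gap_angle_tol_deg`` of the segment's own principal axis;
    segments with no admissible bridge stay detached (they are dropped by
    downstream size filters).
    """
    if config is None:
        config = TracingConfig()
    binary = np.asarray(binary, dtype=bool)
    labels = measure.label(binary | soma.mask, connectivity=2)
    soma_labels = np.unique(labels[soma.mask])
    soma_labels = soma_labels[soma_labels > 0]
    connected = np.isin(labels, soma_labels)
    anchors = np.argwhere(connected)
    out = binary.copy()
    cy, cx = soma.centroid
    tol = np.deg2rad(config.gap_angle_tol_deg)
    for lab in np.unique(labels):
        if lab == 0 or lab in soma_labels:
            continue
        comp = np.argwhere(labels == lab)
        d_soma = np.hypot(comp[:, 0] - cy, comp[:, 1] - cx)
        p = comp[int(np.argmin(d_soma))]
        axis = _component_orientation(comp)
        vec = anchors - p
        dist = np.hypot(vec[:, 0], vec[:, 1])
        bearing = np.arctan2(vec[:, 0], vec[:, 1])
        ok = np.array(
            [_angle_diff_axis(b, axis) <= tol for b in bearing]
        ) & (dist > 0) & (dist <= config.max_gap_px)
        if not np.any(ok):
            continue
        cand = np.where(ok)[0]
        target = anchors[cand[int(np.argmin(dist[cand]))]]
        rr, cc = draw.line(int(p[0]), int(p[1]), int(target[0]), int(target[1]))
        out[rr, cc] = True
    return out


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    pts = np.argwhere(skel)
    pset = {tuple(p) for p in pts}
    for y, x in pset:
        g.add_node((y, x))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                nb = (y + dy, x + dx)
                if nb in pset:
                    g.add_edge((y, x), nb, weight=float(np.hypot(dy, dx)))
    return g


def build_branches(
    binary: np.ndarray,
    soma: SomaMask,
    config: TracingConfig | None = None,
    intensity_image: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
    frame_index: int = 0,
) -> list[NeuriteBranch]:
    """Decompose the soma-connected skeleton into branches rooted at the soma.

    The dilated soma is removed before skeletonizing. Every skeleton
    component adjacent to the soma becomes one neurite; each of its tips
    yields a branch running from the soma-adjacent root to the tip along the
    shortest skeleton path. Terminal subbranches shorter than
    ``min_terminal_um`` are pruned, neurites with fewer than
    ``min_branch_points`` skeleton points are dropped, and at branch points
    a continuation is only accepted when the emerging branch's median
    intensity is within ``intensity_ratio_band`` of the incoming one
    (crossing disambiguation; applied only when an intensity image is
    given).
    """
    if config is None:
        config = TracingConfig()
    binary = np.asarray(binary, dtype=bool)
    soma_dil = morphology.dilation(soma.mask, morphology.disk(config.soma_dilate_px))
    work = binary & ~soma_dil
    skel = morphology.skeletonize(work)
    if not skel.any():
        return []
    labels = measure.label(skel, connectivity=2)
    dist_to_soma = ndimage.distance_transform_edt(~soma_dil)
    branches: list[NeuriteBranch] = []
    branch_counter = 0
    for lab in range(1, labels.max() + 1):
        comp_mask = labels == lab
        if dist_to_soma[comp_mask].min() > config.root_max_dist_px:
            continue  # not rooted at the soma
        if comp_mask.sum() < config.min_branch_points:
            continue
        g = _skeleton_graph(comp_mask)
        comp_pts = np.argwhere(comp_mask)
        d_soma = np.hypot(
            comp_pts[:, 0] - soma.centroid[0], comp_pts[:, 1] - soma.centroid[1]
        )
        root = tuple(comp_pts[int(np.argmin(d_soma))])
        lengths, paths = nx.single_source_dijkstra(g, root)
        leaves = [n for n in g.nodes if g.degree[n] == 1 and n != root]
        if not leaves:
            leaves = [max(lengths, key=lengths.get)]
        cand = []
        for leaf in leaves:
            path = paths[leaf]
            cand.append(path)
        # prune terminal subbranches shorter than min_terminal_um
        kept = []
        for path in cand:
            if len(cand) > 1:
                others = [set(p) for p in cand if p is not path]
                shared = 0
                for i, node in enumerate(path):
                    if any(node in o for o in others):
                        shared = i
                terminal_px = _polyline_length(path[shared:])
                if terminal_px * pixel_size_um < config.min_terminal_um:
                    continue
            kept.append(path)
        # crossing disambiguation by intensity similarity at the branch point
        if intensity_image is not None and len(kept) > 1:
            kept = _filter_crossings(kept, intensity_image, config)
        for path in kept:
            pts = np.array(path)
            inten = (
                intensity_image[pts[:, 0], pts[:, 1]].astype(float)
                if intensity_image is not None
                else None
            )
            branches.append(
                NeuriteBranch(
                    points=pts,
                    pixel_size_um=pixel_size_um,
                    neurite_id=lab - 1,
                    branch_id=branch_counter,
                    intensity=inten,
                    frame=frame_index,
                )
            )
            branch_counter += 1
    return branches


def _polyline_length(path: list[tuple[int, int]]) -> float:
    if len(path) < 2:
        return 0.0
    pts = np.asarray(path, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _filter_crossings(
    paths: list[list[tuple[int, int]]],
    intensity: np.ndarray,
    config: TracingConfig,
    window: int = 10,
) -> list[list[tuple[int, int]]]:
    """Drop branches whose post-branch-point intensity falls outside the
    configured ratio band of the incoming segment (likely a crossing, not a
    branching)."""
    lo, hi = config.intensity_ratio_band
    kept = []
    for path in paths:
        others = [set(p) for p in paths if p is not path]
        shared = 0
        for i, node in enumerate(path):
            if any(node in o for o in others):
                shared = i
        if shared == 0 or shared >= len(path) - 1:
            kept.append(path)
            continue
        inc = path[max(0, shared - window) : shared + 1]
        out = path[shared : shared + window + 1]
        inc_med = float(np.median([intensity[p] for p in inc]))
        out_med = float(np.median([intensity[p] for p in out]))
        if inc_med <= 0:
            kept.append(path)
            continue
        ratio = out_med / inc_med
        if lo <= ratio <= hi:
            kept.append(path)
    return kept if kept else paths[:1]


def trace_frame(
    frame: np.ndarray,
    config: TracingConfig | None = None,
    pixel_size_um: float = 1.0,
    frame_index: int = 0,
) -> list[NeuriteBranch]:
    """Full per-frame pipeline: soma, threshold, gap closing, branches."""
    if config is None:
        config = TracingConfig()
    soma = extract_soma(frame, config)
    thr = find_neuron_threshold(frame, soma, config)
    binary = close_gaps(np.asarray(frame, dtype=float) > thr, soma, config)
    return build_branches(
        binary,
        soma,
        config,
        intensity_image=np.asarray(frame, dtype=float),
        pixel_size_um=pixel_size_um,
        frame_index=frame_index,
    )


def _branch_overlap(a: NeuriteBranch, b: NeuriteBranch) -> float:
    """Share of ``a``'s points lying within a 1-px dilation of ``b``."""
    bset = set()
    for y, x in b.points:
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                bset.add((y + dy, x + dx))
    hits = sum(1 for p in a.points if tuple(p) in bset)
    return hits / max(1, len(a.points))


def filter_overlapping_branches(
    branches_by_frame: dict[int, list[NeuriteBranch]],
    config: TracingConfig | None = None,
) -> dict[int, list[NeuriteBranch]]:
    """Across frames, exclude branch pairs that overlap at least
    ``overlap_frac`` while starting from clearly different origins —
    typically one of them is a mistraced neurite."""
    if config is None:
        config = TracingConfig()
    all_branches = [
        (f, b) for f, blist in branches_by_frame.items() for b in blist
    ]
    bad: set[tuple[int, int]] = set()
    for i, (fa, a) in enumerate(all_branches):
        for fb, b in all_branches[i + 1 :]:
            if fa == fb:
                continue
            origin_dist = np.linalg.norm(
                a.points[0].astype(float) - b.points[0].astype(float)
            )
            if origin_dist <= 3:
                continue
            if max(_branch_overlap(a, b), _branch_overlap(b, a)) >= config.overlap_frac:
                bad.add((fa, a.branch_id))
                bad.add((fb, b.branch_id))
    return {
        f: [b for b in blist if (f, b.branch_id) not in bad]
        for f, blist in branches_by_frame.items()
    }
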