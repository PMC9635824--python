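"""Microtubule orientation from EB3 comet tracks.

A growing microtubule plus end carries an EB3 comet, so the travel
direction of a comet along a neurite reports the orientation of its
microtubule: tip-ward comets are plus-end-out, soma-ward comets are
minus-end-out. Comet detection and tracking are external; this module
consumes finished tracks, reconstructs the neuron from them, and assigns
an orientation to each track relative to traced neurite skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .core import Track

__all__ = [
    "OrientationConfig",
    "OrientationCall",
    "NeuriteSkeleton",
    "tracks_to_neuron_image",
    "classify_comet",
    "orientation_summary",
]


@dataclass
class OrientationConfig:
    max_assign_dist_px: float = 5.0
    consensus_fraction: float = 0.65
    angle_plus_deg: float = 70.0  # below: plus-end-out vote
    angle_minus_deg: float = 110.0  # above: minus-end-out vote
    include_nonvoting: bool = False  # count 70-110 deg timepoints in the denominator
    comet_step: int = 2  # comet direction from t to t + comet_step
    neurite_window: int = 2  # neurite direction from -window to +window points


@dataclass
class OrientationCall:
    comet_id: int
    label: str  # plus_end_out | minus_end_out | undetermined | unassigned
    vote_share: float
    votes_plus: int
    votes_minus: int
    method: str  # endpoint | angle | none


@dataclass
class NeuriteSkeleton:
    """Ordered neurite skeleton points with arc length from the soma.

    ``neurites`` is a list of ``(N_i, 2)`` float point arrays ordered from
    the soma outward; arc lengths are per-point cumulative path lengths in
    pixels (orientation calls only compare arc lengths, so pixel units
    suffice).
    """

    neurites: list[np.ndarray]
    _tree: cKDTree = field(init=False, repr=False)
    _index: np.ndarray = field(init=False, repr=False)
    _arclen: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.neurites:
            raise ValueError("skeleton needs at least one neurite")
        self.neurites = [np.asarray(p, dtype=float) for p in self.neurites]
        pts = np.vstack(self.neurites)
        self._tree = cKDTree(pts)
        self._index = np.concatenate(
            [
                np.column_stack([np.full(len(p), ni), np.arange(len(p))])
                for ni, p in enumerate(self.neurites)
            ]
        ).astype(int)
        self._arclen = [
            np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))]
            )
            for p in self.neurites
        ]

    @classmethod
    def from_paths(cls, paths) -> "NeuriteSkeleton":
        """Build from simulator paths or traced branches (anything with
        ordered soma-to-tip ``points``)."""
        return cls([np.asarray(p.points, dtype=float) for p in paths])

    def nearest(self, point: np.ndarray) -> tuple[int, int, float]:
        """(neurite index, point index, distance) of the closest point."""
        d, i = self._tree.query(np.asarray(point, dtype=float))
        ni, pi = self._index[int(i)]
        return int(ni), int(pi), float(d)

    def arclen(self, neurite: int, idx: int) -> float:
        return float(self._arclen[neurite][idx])

    def direction(self, neurite: int, idx: int, window: int = 2) -> np.ndarray:
        """Local tip-ward unit direction around a skeleton point, taken from
        ``window`` points before to ``window`` points after."""
        pts = self.neurites[neurite]
        lo = max(0, idx - window)
        hi = min(len(pts) - 1, idx + window)
        v = pts[hi] - pts[lo]
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


def tracks_to_neuron_image(
    tracks: list[Track], shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Binary image of the neuron accumulated from all comet track points
    of all time points, dilated by one pixel, keeping the largest connected
    component; the result feeds the tracing module for skeletons."""
    if not tracks:
        raise ValueError("empty track set")
    pts = np.vstack([t.points for t in tracks if t.points is not None])
    if len(pts) == 0:
        raise ValueError("tracks carry no spatial points")
    if shape is None:
        shape = (int(pts[:, 0].max()) + 4, int(pts[:, 1].max()) + 4)
    img = np.zeros(shape, dtype=bool)
    iy = np.clip(np.rint(pts[:, 0]).astype(int), 0, shape[0] - 1)
    ix = np.clip(np.rint(pts[:, 1]).astype(int), 0, shape[1] - 1)
    img[iy, ix] = True
    img = morphology.dilation(img, morphology.disk(1))
    labels = measure.label(img, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no component in accumulated track image")
    areas = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(areas)) + 1)


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def classify_comet(
    track: Track,
    skeleton: NeuriteSkeleton,
    config: OrientationConfig | None = None,
) -> OrientationCall:
    """Orientation of one comet track relative to the neurite skeleton.

    Endpoint rule first: the nearest skeleton points of the first and last
    track points are compared by arc length from the soma — farther = the
    microtubule is plus-end-out, closer = minus-end-out. When first and
    last map to the same skeleton point, per-timepoint angle votes decide:
    the angle between the comet direction (t to t+2) and the local tip-ward
    neurite direction (two points before to two after) votes plus-end-out
    below 70 deg and minus-end-out above 110 deg. The winning orientation
    must reach the consensus fraction (65% of voting timepoints by
    default), otherwise the call is undetermined. Tracks farther than the
    assignment distance from any skeleton point are unassigned.
    """
    if config is None:
        config = OrientationConfig()
    if track.points is None or track.n_timepoints < 3:
        raise ValueError("orientation needs a track of >= 3 frames with points")
    pts = track.points
    ni0, pi0, d0 = skeleton.nearest(pts[0])
    ni1, pi1, d1 = skeleton.nearest(pts[-1])
    if min(d0, d1) > config.max_assign_dist_px:
        return OrientationCall(track.entity_id, "unassigned", 0.0, 0, 0, "none")

    if (ni0, pi0) != (ni1, pi1):
        s0 = skeleton.arclen(ni0, pi0)
        s1 = skeleton.arclen(ni1, pi1)
        if ni0 == ni1 and s1 != s0:
            label = "plus_end_out" if s1 > s0 else "minus_end_out"
            return OrientationCall(track.entity_id, label, 1.0, 0, 0, "endpoint")
        # different neurites (through the soma) — ambiguous endpoint rule,
        # fall through to angle voting

    votes_plus = votes_minus = no_vote = 0
    step = config.comet_step
    for t in range(track.n_timepoints - step):
        comet_dir = pts[t + step] - pts[t]
        ni, pi, d = skeleton.nearest(pts[t])
        if d > config.max_assign_dist_px:
            no_vote += 1
            continue
        neur_dir = skeleton.direction(ni, pi, config.neurite_window)
        ang = _angle_deg(comet_dir, neur_dir)
        if not np.isfinite(ang):
            no_vote += 1
        elif ang < config.angle_plus_deg:
            votes_plus += 1
        elif ang > config.angle_minus_deg:
            votes_minus += 1
        else:
            no_vote += 1
    denom = votes_plus + votes_minus + (no_vote if config.include_nonvoting else 0)
    if denom == 0:
        return OrientationCall(track.entity_id, "undetermined", 0.0, 0, 0, "angle")
    share = max(votes_plus, votes_minus) / denom
    if share >= config.consensus_fraction:
        label = "plus_end_out" if votes_plus >= votes_minus else "minus_end_out"
    else:
        label = "undetermined"
    return OrientationCall(track.entity_id, label, share, votes_plus, votes_minus, "angle")


def orientation_summary(calls: list[OrientationCall]) -> dict:
    """Fractions over the three labels (plus-end-out, minus-end-out,
    undetermined; unassigned calls are excluded) plus the plus-end-out
    fraction among determined calls."""
    counted = [c for c in calls if c.label != "unassigned"]
    n = len(counted)
    n_plus = sum(c.label == "plus_end_out" for c in counted)
    n_minus = sum(c.label == "minus_end_out" for c in counted)
    n_und = n - n_plus - n_minus
    det = n_plus + n_minus
    return {
        "n": n,
        "n_unassigned": len(calls) - n,
        "fraction_plus_end_out": n_plus / n if n else float("nan"),
        "fraction_minus_end_out": n_minus / n if n else float("nan"),
        "fraction_undetermined": n_und / n if n else float("nan"),
        "plus_fraction_of_determined": n_plus / det if det else float("nan"),
    }
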