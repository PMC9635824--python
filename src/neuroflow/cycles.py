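"""Microtubule density cycles.

Per-neurite tubulin intensity is normalized by the neuron's tubulin
expression level — modeled as a low-order polynomial fit of the average
intensity over all neurites against time — giving a dimensionless density
around 1. A density excursion of at least 0.2 counts as half a cycle; a
full cycle is an increase of 0.2 followed by a decrease of 0.2 or vice
versa, and the cycle frequency is full cycles divided by the trace
duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DensityTrace",
    "CycleCount",
    "expression_fit",
    "normalize_density",
    "smooth_trace",
    "count_cycles",
    "cycle_frequency_per_cell",
    "correlate_flow_cycles",
]


@dataclass
class DensityTrace:
    """Normalized (dimensionless) microtubule density of one neurite."""

    values: np.ndarray
    frame_interval_s: float
    neurite_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def duration_h(self) -> float:
        return (len(self.values) - 1) * self.frame_interval_s / 3600.0


@dataclass
class CycleCount:
    half_swings: int
    full_cycles: int  # completed increase+decrease pairs, = half_swings // 2
    frequency_per_hour: float  # (half_swings / 2) / duration_h
    duration_h: float


def expression_fit(avg_intensity: np.ndarray, degree: int = 2) -> np.ndarray:
    """Tubulin expression level over time: least-squares polynomial fit
    (degree 2 for long developmental movies, degree 1 for short drug-
    treatment movies) of the neurite-averaged intensity.

    Raises if the fitted expression is nonpositive anywhere, since the
    normalization would be undefined.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(avg_intensity, dtype=float)
    if len(y) < degree + 2:
        raise ValueError(f"need at least {degree + 2} frames for degree {degree}")
    t = np.arange(len(y), dtype=float)
    coef = np.polyfit(t, y, degree)
    fitted = np.polyval(coef, t)
    if np.any(fitted <= 0):
        raise ValueError("fitted expression level is nonpositive; cannot normalize")
    return fitted


def normalize_density(
    neurite_intensity: np.ndarray,
    expression: np.ndarray,
    frame_interval_s: float,
    neurite_id: int = 0,
) -> DensityTrace:
    """Density = per-neurite mean intensity / fitted expression level."""
    y = np.asarray(neurite_intensity, dtype=float)
    e = np.asarray(expression, dtype=float)
    if y.shape != e.shape:
        raise ValueError("intensity and expression series must align")
    return DensityTrace(values=y / e, frame_interval_s=frame_interval_s, neurite_id=neurite_id)


def smooth_trace(trace: DensityTrace, window: int = 2) -> DensityTrace:
    """Trailing rolling mean: each frame is averaged with the ``window - 1``
    preceding frames (the first frames use what exists)."""
    v = trace.values
    out = np.empty_like(v)
    for i in range(len(v)):
        out[i] = v[max(0, i - window + 1) : i + 1].mean()
    return DensityTrace(out, trace.frame_interval_s, trace.neurite_id)


def count_cycles(trace: DensityTrace, delta: float = 0.2) -> CycleCount:
    """Count density half-swings and full cycles with a hysteresis detector.

    The detector tracks the running extremum; when the trace departs from
    it by at least ``delta`` in the opposite direction, a half-swing is
    recorded and the extremum resets to the current value. Alternation is
    guaranteed by construction, so the completed-cycle count is
    half-swings // 2. Each excursion counts as half a cycle, so the
    frequency is ``(half_swings / 2) / duration``: rounding the trailing
    unpaired excursion down instead would systematically underestimate the
    frequency of finite traces by up to half a cycle.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    v = trace.values
    half = 0
    state = 0  # 0 undecided, +1 looking for a drop (tracking max), -1 rise
    run_max = run_min = v[0]
    for x in v[1:]:
        if state >= 0:
            run_max = max(run_max, x)
        if state <= 0:
            run_min = min(run_min, x)
        if state == 0:
            if run_max - x >= delta:
                half += 1
                state = -1  # next: look for a rise from the running min
                run_min = x
            elif x - run_min >= delta:
                half += 1
                state = 1
                run_max = x
        elif state == 1:  # waiting for a drop of delta from the running max
            if run_max - x >= delta:
                half += 1
                state = -1
                run_min = x
        else:  # waiting for a rise of delta from the running min
            if x - run_min >= delta:
                half += 1
                state = 1
                run_max = x
    full = half // 2
    dur = trace.duration_h
    freq = (half / 2.0) / dur if dur > 0 else float("nan")
    return CycleCount(half_swings=half, full_cycles=full, frequency_per_hour=freq, duration_h=dur)


def cycle_frequency_per_cell(
    traces: list[DensityTrace],
    delta: float = 0.2,
    smooth_window: int = 2,
    include: list[int] | None = None,
) -> float:
    """Mean cycle frequency (cycles/hour) over a cell's neurites.

    ``include`` restricts to a neurite subset (e.g. minor neurites only,
    excluding the axon); by default every trace counts.
    """
    sel = [
        tr for tr in traces if include is None or tr.neurite_id in include
    ]
    if not sel:
        raise ValueError("no traces selected")
    freqs = [
        count_cycles(smooth_trace(tr, smooth_window), delta).frequency_per_hour
        for tr in sel
    ]
    return float(np.mean(freqs))


def correlate_flow_cycles(
    flow: np.ndarray, cycles_per_hour: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-neurite MT-RF speed
    against cycle frequency; pairs with missing values are dropped, and a
    constant input yields (nan, nan)."""
    x = np.asarray(flow, dtype=float)
    y = np.asarray(cycles_per_hour, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arrays must align")
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
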