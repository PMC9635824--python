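"""Independent oracles used by the tests (kept separate from the package
implementations they check)."""

from __future__ import annotations

import numpy as np


def fft_exhaustive_shift(
    reference: np.ndarray, frame: np.ndarray, radius: int = 10
) -> tuple[int, int]:
    """Exhaustive cyclic-correlation search over all shifts within
    ``radius``, via FFT cross-correlation of the mean-subtracted frames
    (Pearson correlation under cyclic rolls is a monotone function of the
    circular cross-correlation)."""
    r0 = reference - reference.mean()
    f0 = frame - frame.mean()
    cc = np.real(np.fft.ifft2(np.fft.fft2(r0) * np.conj(np.fft.fft2(f0))))
    best, best_val = (0, 0), -np.inf
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            v = cc[dy % cc.shape[0], dx % cc.shape[1]]
            if v > best_val:
                best_val, best = v, (dy, dx)
    return best


def dp_max_alternations(x: np.ndarray, delta: float = 0.2) -> int:
    """Maximum number of alternating moves of magnitude >= delta over any
    subsequence of ``x`` (dynamic program; independent of the hysteresis
    swing detector it checks)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    up = np.full(n, -1)
    dn = np.full(n, -1)
    for i in range(1, n):
        diffs = x[i] - x[:i]
        rise = diffs >= delta
        fall = diffs <= -delta
        if rise.any():
            up[i] = np.maximum(dn[:i][rise], 0).max() + 1
        if fall.any():
            dn[i] = np.maximum(up[:i][fall], 0).max() + 1
    return int(max(0, up.max(), dn.max()))


def polyline_length(points: np.ndarray) -> float:
    """Sum of point-to-point Euclidean step lengths."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
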