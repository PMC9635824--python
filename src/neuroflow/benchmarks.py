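"""Parameter-recovery experiments on the synthetic benchmark.

Each driver generates seeded synthetic data at stated ground-truth
conditions, runs the corresponding analysis pipeline exactly as it would
run on real data, and returns the recovered per-unit values so callers can
summarize them. All randomness derives from one integer seed.
"""

from __future__ import annotations

import numpy as np

from .cycles import correlate_flow_cycles, count_cycles, smooth_trace
from .flow import FlowConfig, mass_distribution, speed_from_track, track_patch
from .registration import RegistrationConfig, register_movie
from .synthetic import (
    SimConfig,
    simulate_density_traces,
    simulate_mass_kymograph,
    simulate_patch_movie,
)

__all__ = [
    "recover_patch_speeds",
    "paired_regime_recovery",
    "distal_excess_recovery",
    "cycle_frequency_recovery",
    "mass_partition_recovery",
    "correlation_recovery",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _movie_config(seed: int, drift_um_min: float) -> SimConfig:
    """Single-neurite photoconversion movie at the standard imaging regime:
    0.22 um/px, 30-s frames, 10 min, SNR ~5, jitter up to +-3 px/frame."""
    return SimConfig(
        seed=int(seed),
        n_neurites=1,
        neurite_length_um=20.0,
        patch_init_um=(14.0,),
        patch_speed_um_min=(drift_um_min,),
        jitter_max_px=3,
        noise_gaussian_sd=15.0,
        poisson_gain=1.0,
        bleach_rate_per_min=0.02,
    )


def _recover_one(config: SimConfig, register: bool = True) -> list[float]:
    """Run cap/register -> patch tracking -> speed on one movie; returns the
    recovered speed magnitude of each simulated patch (um/min)."""
    movie, truth = simulate_patch_movie(config)
    if register:
        registered, _ = register_movie(
            movie, RegistrationConfig(channel="tubulin")
        )
    else:
        registered = movie
    flow_cfg = FlowConfig()
    speeds = []
    for p in range(len(config.patch_init_um)):
        path = truth.paths[config.patch_neurite[p]]
        track = track_patch(
            registered.single("converted"),
            path,
            flow_cfg,
            start_um=config.patch_init_um[p],
        )
        speeds.append(speed_from_track(track, flow_cfg).speed_um_min)
    return speeds


def recover_patch_speeds(
    drift_um_min: float, n_movies: int, seed: int, register: bool = True
) -> np.ndarray:
    """Recovered retrograde patch speeds from ``n_movies`` seeded
    single-neurite movies drifting at ``drift_um_min`` (soma-ward)."""
    out = []
    for s in _child_seeds(seed, n_movies):
        cfg = _movie_config(s, -abs(drift_um_min))
        out.append(_recover_one(cfg, register=register)[0])
    return np.asarray(out)


def paired_regime_recovery(
    minor_um_min: float, axon_um_min: float, n_cells: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paired simulation of polarized neurons: per cell, two minor-neurite
    movies at the minor regime mean and one axon movie at the axon regime
    mean. Returns (per-cell minor means, per-cell axon speeds)."""
    seeds = _child_seeds(seed, 3 * n_cells).reshape(n_cells, 3)
    minors, axons = [], []
    for row in seeds:
        m1 = _recover_one(_movie_config(row[0], -abs(minor_um_min)))[0]
        m2 = _recover_one(_movie_config(row[1], -abs(minor_um_min)))[0]
        ax = _recover_one(_movie_config(row[2], -abs(axon_um_min)))[0]
        minors.append((m1 + m2) / 2.0)
        axons.append(ax)
    return np.asarray(minors), np.asarray(axons)


def distal_excess_recovery(
    base_um_min: float, excess_percent: float, n_neurites: int, seed: int
) -> np.ndarray:
    """Two patches per neurite, the distal one drifting ``excess_percent``
    faster than the proximal one; returns the per-neurite recovered percent
    excess of the distal over the proximal speed."""
    out = []
    for s in _child_seeds(seed, n_neurites):
        distal_speed = base_um_min * (1.0 + excess_percent / 100.0)
        cfg = SimConfig(
            seed=int(s),
            shape=(280, 280),
            n_neurites=1,
            neurite_length_um=30.0,
            patch_init_um=(8.0, 22.0),
            patch_speed_um_min=(-base_um_min, -distal_speed),
            patch_neurite=(0, 0),
            jitter_max_px=0,
            noise_gaussian_sd=15.0,
            poisson_gain=1.0,
            bleach_rate_per_min=0.02,
        )
        vp, vd = _recover_one(cfg, register=False)
        out.append((vd - vp) / vp * 100.0)
    return np.asarray(out)


def cycle_frequency_recovery(
    cycles_per_hour: float,
    n_cells: int,
    n_neurites: int,
    seed: int,
    amplitude: float = 0.25,
    noise_sd: float = 0.03,
    duration_h: float = 10.0,
    frame_interval_s: float = 180.0,
) -> np.ndarray:
    """Per-cell mean recovered cycle frequency from triangle-wave density
    traces oscillating at ``cycles_per_hour``."""
    out = []
    for s in _child_seeds(seed, n_cells):
        cfg = SimConfig(
            seed=int(s), n_neurites=n_neurites, frame_interval_s=frame_interval_s
        )
        traces, _ = simulate_density_traces(
            cfg,
            period_h=1.0 / cycles_per_hour,
            amplitude=amplitude,
            duration_h=duration_h,
            noise_sd=noise_sd,
        )
        freqs = [
            count_cycles(smooth_trace(tr)).frequency_per_hour for tr in traces
        ]
        out.append(float(np.mean(freqs)))
    return np.asarray(out)


def mass_partition_recovery(
    fractions: tuple[float, float, float], n_kymos: int, seed: int
) -> np.ndarray:
    """Recovered (retro, stationary, antero) fractions per synthetic
    kymograph built at the requested partition."""
    out = []
    for s in _child_seeds(seed, n_kymos):
        cfg = SimConfig(seed=int(s), n_frames=12)
        kymo, truth = simulate_mass_kymograph(cfg, fractions)
        out.append(mass_distribution(kymo, start_px=truth.mass_start_px))
    return np.asarray(out)


def correlation_recovery(
    rho: float, n_cohorts: int, n_pairs: int, seed: int
) -> np.ndarray:
    """Pearson r recovered per cohort of (flow, cycle-frequency) pairs drawn
    from a bivariate normal with population correlation ``rho``."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    out = []
    for _ in range(n_cohorts):
        xy = rng.multivariate_normal([0.5, 0.5], cov * 0.01, size=n_pairs)
        r, _p = correlate_flow_cycles(xy[:, 0], xy[:, 1])
        out.append(r)
    return np.asarray(out)
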