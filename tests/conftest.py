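import numpy as np
import pytest

from neuroflow import SimConfig, simulate_patch_movie


@pytest.fixture(scope="session")
def clean_patch_movie():
    """Noise-free, jitter-free single-neurite photoconversion movie
    (shared across tests; treat as read-only)."""
    cfg = SimConfig(seed=12, noise_gaussian_sd=0.0, poisson_gain=0.0, jitter_max_px=0)
    movie, truth = simulate_patch_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def noisy_jittered_movie():
    """Movie at the standard imaging regime: SNR ~5, +-3 px jitter,
    bleaching on."""
    cfg = SimConfig(
        seed=21,
        noise_gaussian_sd=15.0,
        poisson_gain=1.0,
        jitter_max_px=3,
        bleach_rate_per_min=0.02,
    )
    movie, truth = simulate_patch_movie(cfg)
    return cfg, movie, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
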