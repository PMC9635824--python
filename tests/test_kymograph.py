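import numpy as np
import pytest

from neuroflow import (
    Kymograph,
    MovieStack,
    NeuritePath,
    SimConfig,
    neurite_length_series,
    proximal_distal_density,
    sample_kymograph,
    simulate_patch_movie,
    soma_fraction,
)


def _straight_path(n=60, row=30, col0=5, px=0.22):
    pts = np.column_stack([np.full(n, row, dtype=float), col0 + np.arange(n, dtype=float)])
    return NeuritePath(pts, px)


class TestSampleKymograph:
    def test_uniform_movie_gives_uniform_kymograph(self):
        movie = MovieStack(np.full((4, 60, 80), 3.5), 0.22, 30.0)
        kymo = sample_kymograph(movie, _straight_path(), 11)
        assert np.allclose(kymo.data, 3.5)
        assert kymo.n_frames == 4

    def test_bright_pixel_appears_at_its_arclength(self):
        data = np.zeros((3, 60, 80))
        data[1, 30, 5 + 17] = 9.0  # on the path, 17 px from its origin
        movie = MovieStack(data, 0.22, 30.0)
        kymo = sample_kymograph(movie, _straight_path(), 11)
        t, s = np.unravel_index(np.argmax(kymo.data), kymo.data.shape)
        assert (t, s) == (1, 17)

    def test_width_must_be_odd(self):
        movie = MovieStack(np.zeros((2, 40, 40)), 0.22, 30.0)
        with pytest.raises(ValueError):
            sample_kymograph(movie, _straight_path(n=20), 10)

    def test_ridge_slope_matches_simulated_drift(self):
        cfg = SimConfig(seed=4, noise_gaussian_sd=0.0, poisson_gain=0.0, jitter_max_px=0)
        movie, truth = simulate_patch_movie(cfg)
        kymo = sample_kymograph(movie.single("converted"), truth.paths[0], 11)
        ridge_um = np.argmax(kymo.data, axis=1) * kymo.pixel_size_um
        t_min = np.arange(cfg.n_frames) * cfg.frame_interval_s / 60.0
        slope = np.polyfit(t_min, ridge_um, 1)[0]
        assert slope == pytest.approx(-0.53, abs=0.05)

    def test_intensity_monotone(self):
        rng = np.random.default_rng(3)
        movie = MovieStack(rng.uniform(0, 10, (3, 60, 80)), 0.22, 30.0)
        k1 = sample_kymograph(movie, _straight_path(), 11)
        scaled = MovieStack(movie.data * 2.5, 0.22, 30.0)
        k2 = sample_kymograph(scaled, _straight_path(), 11)
        assert np.allclose(k2.data, 2.5 * k1.data)


class TestNeuriteLengthSeries:
    def test_stop_one_pixel_before_gap(self):
        # border-open gap beyond column 2 survives hole filling; the first
        # and last time points are forced fully thresholded by design
        data = np.tile([5.0, 5.0, 5.0, 0.0, 0.0], (4, 1))
        kymo = Kymograph(data, 0.22, 30.0)
        lengths = neurite_length_series(kymo, threshold=1.0, smooth_mode="rowwise5")
        assert np.allclose(lengths[1:-1], 2 * 0.22)
        assert np.allclose(lengths[[0, -1]], 4 * 0.22)

    def test_fully_thresholded_row(self):
        kymo = Kymograph(np.full((3, 50), 5.0), 0.22, 30.0)
        assert np.allclose(neurite_length_series(kymo, threshold=1.0), 49 * 0.22)

    def test_all_background_frame_is_zero(self):
        data = np.full((5, 30), 5.0)
        data[2] = 0.0
        kymo = Kymograph(data, 0.22, 30.0)
        lengths = neurite_length_series(kymo, threshold=1.0, smooth_mode="rowwise5")
        assert lengths[2] == 0.0

    def test_enclosed_hole_is_filled(self):
        data = np.full((5, 30), 5.0)
        data[2, 10] = 0.0  # transient dropout, enclosed in time and space
        kymo = Kymograph(data, 0.22, 30.0)
        lengths = neurite_length_series(kymo, threshold=1.0, smooth_mode="rowwise5")
        assert np.allclose(lengths, 29 * 0.22)

    def test_retraction_recovered(self):
        # ridge shortens by 5 um over the movie; compare interior frames
        # (the first/last rows are forced fully thresholded by design)
        px, n_cols, n_rows = 0.22, 120, 12
        data = np.zeros((n_rows, n_cols))
        true = {}
        for t in range(n_rows):
            length_um = 20.0 - 5.0 * t / (n_rows - 1)
            data[t, : int(round(length_um / px))] = 8.0
            true[t] = length_um
        kymo = Kymograph(data, px, 60.0)
        lengths = neurite_length_series(kymo, threshold=1.0, smooth_mode="rowwise5")
        drop = lengths[1] - lengths[-2]
        assert drop == pytest.approx(true[1] - true[n_rows - 2], abs=2 * px)

    def test_threshold_scale_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 10, (6, 40))
        k1 = Kymograph(data, 0.22, 30.0)
        k2 = Kymograph(data * 3.0, 0.22, 30.0)
        l1 = neurite_length_series(k1, threshold=4.0)
        l2 = neurite_length_series(k2, threshold=12.0)
        assert np.array_equal(l1, l2)

    def test_lengths_bounded_by_kymograph(self):
        rng = np.random.default_rng(6)
        kymo = Kymograph(rng.uniform(0, 10, (8, 55)), 0.22, 30.0)
        lengths = neurite_length_series(kymo, threshold=5.0)
        assert np.all(lengths >= 0)
        assert np.all(lengths <= (55 - 1) * 0.22)


class TestProximalDistalDensity:
    def test_uniform_kymograph_normalizes_to_one(self):
        kymo = Kymograph(np.full((10, 100), 6.0), 0.22, 90.0)
        lengths = np.full(10, 100 * 0.22 - 0.22)
        prox, dist = proximal_distal_density(kymo, lengths, threshold=1.0)
        assert np.allclose(prox, 1.0)
        assert np.allclose(dist, 1.0)

    def test_doubled_distal_zone(self):
        px = 0.22
        n_cols = 100
        lengths = np.full(6, (n_cols - 1) * px)
        data = np.full((6, n_cols), 5.0)
        L = lengths[0]
        lo = int(np.ceil((L - 10.0) / px))
        hi = int(np.floor((L - 5.0) / px))
        data[:, lo : hi + 1] = 10.0
        kymo = Kymograph(data, px, 90.0)
        prox, dist = proximal_distal_density(kymo, lengths, threshold=1.0)
        # both normalize to 1; the raw ratio is checked pre-normalization
        raw_prox = data[0, : int(5.0 / px) + 1].mean()
        raw_dist = data[0, lo : hi + 1].mean()
        assert raw_dist == pytest.approx(2 * raw_prox)
        assert np.allclose(prox, 1.0) and np.allclose(dist, 1.0)

    def test_short_neurite_has_missing_distal(self):
        kymo = Kymograph(np.full((4, 60), 6.0), 0.22, 90.0)
        lengths = np.full(4, 8.0)  # 8-um neurite
        prox, dist = proximal_distal_density(kymo, lengths, threshold=1.0)
        assert np.all(np.isfinite(prox))
        assert np.all(np.isnan(dist))


class TestSomaFraction:
    def _regions(self, shape=(40, 40)):
        soma = np.zeros(shape, dtype=bool)
        soma[:, :20] = True
        cell = np.ones(shape, dtype=bool)
        return soma, cell

    def test_all_fluorescence_in_soma(self):
        soma, cell = self._regions()
        data = np.zeros((3, 40, 40))
        data[:, 5:15, 5:15] = 10.0
        movie = MovieStack(data, 0.22, 60.0)
        f = soma_fraction(movie, soma, cell, threshold=5.0, background=0.0)
        assert np.allclose(f, 1.0)

    def test_half_and_half(self):
        soma, cell = self._regions()
        data = np.zeros((2, 40, 40))
        data[:, 10:20, 10:15] = 8.0  # inside soma half
        data[:, 10:20, 25:30] = 8.0  # outside
        movie = MovieStack(data, 0.22, 60.0)
        f = soma_fraction(movie, soma, cell, threshold=5.0, background=0.0)
        assert np.allclose(f, 0.5)

    def test_relocalization_crossing(self):
        soma, cell = self._regions()
        n = 11
        data = np.zeros((n, 40, 40))
        for t in range(n):
            w = t  # soma share grows linearly 0..1
            data[t, 10:20, 10:20] = w
            data[t, 10:20, 25:35] = n - 1 - w
        movie = MovieStack(data + 0.0, 0.22, 60.0)
        f = soma_fraction(movie, soma, cell, threshold=0.5, background=0.0)
        crossing = int(np.argmax(f >= 0.25))
        assert abs(crossing - 2.5) <= 1.0  # 0.25 of 10 -> between frames 2 and 3

    def test_zero_fluorescence_missing(self):
        soma, cell = self._regions()
        movie = MovieStack(np.zeros((2, 40, 40)), 0.22, 60.0)
        f = soma_fraction(movie, soma, cell, threshold=1.0, background=0.0)
        assert np.all(np.isnan(f))

    def test_soma_must_be_inside_cell(self):
        soma, cell = self._regions()
        with pytest.raises(ValueError):
            soma_fraction(
                MovieStack(np.zeros((1, 40, 40)), 0.22, 60.0), cell, soma, 1.0
            )
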