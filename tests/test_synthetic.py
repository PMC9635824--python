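"""The synthetic generators must honor their own ground truth: that is the
foundation every recovery test stands on."""

import numpy as np
import pytest
from scipy import stats

from neuroflow import (
    SimConfig,
    simulate_camsap_movie,
    simulate_comet_tracks,
    simulate_density_traces,
    simulate_mass_kymograph,
    simulate_patch_movie,
)
from neuroflow.cycles import count_cycles, smooth_trace


def _centroid(img):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    tot = img.sum()
    return np.array([(img * yy).sum() / tot, (img * xx).sum() / tot])


class TestSimConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(pixel_size_um=0.0)
        with pytest.raises(ValueError):
            SimConfig(frame_interval_s=-1.0)
        with pytest.raises(ValueError):
            SimConfig(n_frames=1)

    def test_patch_beyond_neurite_rejected(self):
        cfg = SimConfig(neurite_length_um=10.0, patch_init_um=(25.0,), seed=0)
        with pytest.raises(ValueError, match="exceeds neurite length"):
            simulate_patch_movie(cfg)


class TestPatchMovie:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(seed=5, noise_gaussian_sd=8.0, poisson_gain=1.0, jitter_max_px=2)
        m1, t1 = simulate_patch_movie(cfg)
        m2, t2 = simulate_patch_movie(cfg)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(t1.jitter_px, t2.jitter_px)
        assert np.array_equal(t1.patch_arclen_um, t2.patch_arclen_um)

    def test_stationary_patch_is_static(self):
        cfg = SimConfig(
            seed=3, patch_speed_um_min=(0.0,), noise_gaussian_sd=0.0,
            poisson_gain=0.0, jitter_max_px=0, bleach_rate_per_min=0.0,
        )
        movie, truth = simulate_patch_movie(cfg)
        conv = movie.channel("converted")
        assert np.allclose(conv, conv[0])
        assert np.allclose(truth.patch_arclen_um[0], truth.patch_arclen_um[0, 0])

    def test_drift_speed_times_time(self):
        # -0.5 um/min for 10 min at 30-s frames: 5 um closer to the soma
        cfg = SimConfig(
            seed=3, patch_speed_um_min=(-0.5,), frame_interval_s=30.0, n_frames=21
        )
        _, truth = simulate_patch_movie(cfg)
        s = truth.patch_arclen_um[0]
        assert s[-1] == pytest.approx(s[0] - 5.0, abs=1e-9)

    def test_true_positions_fit_slope(self):
        # least-squares line through the true positions recovers the drift
        cfg = SimConfig(seed=9, patch_speed_um_min=(-0.53,))
        _, truth = simulate_patch_movie(cfg)
        t_min = np.arange(cfg.n_frames) * cfg.frame_interval_s / 60.0
        slope = np.polyfit(t_min, truth.patch_arclen_um[0], 1)[0]
        assert slope == pytest.approx(-0.53, abs=1e-9)

    def test_mass_conservation_without_bleach_and_noise(self, clean_patch_movie):
        _, movie, _ = clean_patch_movie
        sums = movie.channel("converted").sum(axis=(1, 2))
        assert np.allclose(sums, sums[0], rtol=1e-9)

    def test_centroid_matches_ground_truth(self, clean_patch_movie):
        _, movie, truth = clean_patch_movie
        conv = movie.channel("converted")
        for t in range(0, movie.n_frames, 5):
            c = _centroid(conv[t])
            assert np.linalg.norm(c - truth.patch_xy[0, t]) < 0.25

    def test_jitter_first_frame_zero(self, noisy_jittered_movie):
        _, _, truth = noisy_jittered_movie
        assert np.all(truth.jitter_px[0] == 0)
        assert np.abs(truth.jitter_px).max() <= 3


class TestCamsapMovie:
    def test_single_punctum_slope(self):
        cfg = SimConfig(
            seed=5, camsap_n_puncta=1, camsap_speed_um_min=-0.4, n_frames=15,
            noise_gaussian_sd=0.0, jitter_max_px=0,
        )
        _, truth = simulate_camsap_movie(cfg)
        pos = truth.puncta[0]["arclen_um"]
        good = np.isfinite(pos)
        t_min = np.arange(cfg.n_frames)[good] * cfg.frame_interval_s / 60.0
        slope = np.polyfit(t_min, pos[good], 1)[0]
        assert slope == pytest.approx(-0.4, abs=1e-9)

    def test_slowdown_onset_recorded(self):
        cfg = SimConfig(seed=5, camsap_slowdown_frame=8, frame_interval_s=60.0)
        _, truth = simulate_camsap_movie(cfg)
        assert truth.slowdown_onset_min == pytest.approx(8.0)

    def test_median_of_mixed_speeds(self):
        speeds = (-0.2, -0.3, -0.4, -0.5, -0.8)
        cfg = SimConfig(
            seed=7, n_neurites=5, camsap_speed_um_min=speeds, camsap_n_puncta=2
        )
        _, truth = simulate_camsap_movie(cfg)
        got = [p["speed_um_min"] for p in truth.puncta]
        assert np.median(got) == pytest.approx(np.median(speeds))

    def test_requires_a_punctum(self):
        with pytest.raises(ValueError):
            simulate_camsap_movie(SimConfig(camsap_n_puncta=0))


class TestCometTracks:
    @pytest.mark.parametrize("fraction,label", [(1.0, "plus_end_out"), (0.0, "minus_end_out")])
    def test_pure_fractions(self, fraction, label):
        tracks, truth = simulate_comet_tracks(SimConfig(seed=2, comet_n=40), fraction)
        assert all(lab == label for lab in truth.comet_labels)
        for tr, lab in zip(tracks, truth.comet_labels):
            d = tr.arclen_um[-1] - tr.arclen_um[0]
            assert (d > 0) == (lab == "plus_end_out")

    def test_mixed_fraction_within_binomial_interval(self):
        tracks, truth = simulate_comet_tracks(SimConfig(seed=8, comet_n=200), 0.7)
        k = sum(lab == "plus_end_out" for lab in truth.comet_labels)
        lo, hi = stats.binom.interval(0.99, 200, 0.7)
        assert lo <= k <= hi

    def test_speeds_within_configured_range(self):
        tracks, _ = simulate_comet_tracks(SimConfig(seed=4, comet_n=30), 0.5)
        for tr in tracks:
            v = abs(tr.arclen_um[-1] - tr.arclen_um[0]) / tr.duration_min
            assert 11.0 <= v <= 19.0  # 12-18 um/min nominal, edge clipping allowed

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_comet_tracks(SimConfig(), 1.5)


class TestDensityTraces:
    def test_zero_amplitude_is_flat(self):
        traces, _ = simulate_density_traces(
            SimConfig(seed=1, frame_interval_s=180.0), 2.0, 0.0, noise_sd=0.0
        )
        assert np.allclose(traces[0].values, 1.0)

    def test_exact_cycle_count_in_ground_truth(self):
        _, truth = simulate_density_traces(
            SimConfig(seed=1, frame_interval_s=180.0), 2.0, 0.25, duration_h=10.0
        )
        assert truth.true_full_cycles == pytest.approx(5.0)
        assert truth.true_cycles_per_hour == pytest.approx(0.5)

    def test_subthreshold_amplitude_counts_zero_cycles(self):
        traces, _ = simulate_density_traces(
            SimConfig(seed=1, frame_interval_s=180.0), 2.0, 0.1, noise_sd=0.0
        )
        cc = count_cycles(smooth_trace(traces[0]))
        assert cc.half_swings == 0
        assert cc.frequency_per_hour == 0.0


class TestMassKymograph:
    def test_all_mass_retrograde(self):
        cfg = SimConfig(seed=2)
        kymo, truth = simulate_mass_kymograph(cfg, (1.0, 0.0, 0.0), noise_sd=0.0)
        sub = kymo.data - truth.mass_background
        start, half = truth.mass_start_px, int(np.floor(1.1 / cfg.pixel_size_um + 0.5))
        assert sub[:, start - half :].sum() == pytest.approx(0.0, abs=1e-9)
        assert sub.sum() > 0

    def test_all_mass_stationary(self):
        cfg = SimConfig(seed=2)
        kymo, truth = simulate_mass_kymograph(cfg, (0.0, 1.0, 0.0), noise_sd=0.0)
        sub = kymo.data - truth.mass_background
        start, half = truth.mass_start_px, int(np.floor(1.1 / cfg.pixel_size_um + 0.5))
        inside = sub[:, start - half : start + half + 1].sum()
        assert inside == pytest.approx(sub.sum(), rel=1e-9)

    def test_zone_sums_match_requested_fractions(self):
        # direct zone-summation oracle on the noiseless kymograph
        cfg = SimConfig(seed=3)
        frac = (0.84, 0.06, 0.10)
        kymo, truth = simulate_mass_kymograph(cfg, frac, noise_sd=0.0)
        sub = kymo.data - truth.mass_background
        start, half = truth.mass_start_px, int(np.floor(1.1 / cfg.pixel_size_um + 0.5))
        total = sub.sum()
        got = (
            sub[:, : start - half].sum() / total,
            sub[:, start - half : start + half + 1].sum() / total,
            sub[:, start + half + 1 :].sum() / total,
        )
        # within the discretization of one pixel column of the profile
        col_mass = sub.max() / total * sub.shape[0]
        for g, f in zip(got, frac):
            assert abs(g - f) <= max(1e-9, col_mass)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_mass_kymograph(SimConfig(), (0.5, 0.2, 0.1))
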