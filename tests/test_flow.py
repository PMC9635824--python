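import numpy as np
import pytest

from neuroflow import (
    FlowConfig,
    Kymograph,
    SimConfig,
    Track,
    camsap_flow_series,
    classify_axon,
    detect_slowdown,
    extract_camsap_traces,
    mass_distribution,
    neurite_background,
    patch_spread,
    patch_synchrony,
    sample_kymograph,
    simulate_camsap_movie,
    simulate_mass_kymograph,
    simulate_patch_movie,
    speed_from_track,
    track_patch,
)
from neuroflow.flow import KymoTrace


def _track(arclen, dt_s=30.0, neurite_id=0):
    arclen = np.asarray(arclen, dtype=float)
    return Track(
        frames=np.arange(len(arclen)),
        arclen_um=arclen,
        frame_interval_s=dt_s,
        neurite_id=neurite_id,
    )


class TestTrackPatch:
    def test_stationary_noiseless_patch_constant(self):
        cfg = SimConfig(
            seed=2, patch_speed_um_min=(0.0,), noise_gaussian_sd=0.0,
            poisson_gain=0.0, jitter_max_px=0, bleach_rate_per_min=0.0,
        )
        movie, truth = simulate_patch_movie(cfg)
        tr = track_patch(movie.single("converted"), truth.paths[0])
        assert np.ptp(tr.arclen_um) < 0.05

    def test_positions_match_ground_truth(self, clean_patch_movie):
        cfg, movie, truth = clean_patch_movie
        tr = track_patch(movie.single("converted"), truth.paths[0])
        assert tr.n_timepoints == cfg.n_frames
        err_px = np.abs(tr.arclen_um - truth.patch_arclen_um[0, tr.frames]) / cfg.pixel_size_um
        assert err_px.max() < 0.5

    def test_two_patches_require_explicit_starts(self):
        cfg = SimConfig(
            seed=6, shape=(280, 280), neurite_length_um=30.0,
            patch_init_um=(8.0, 22.0), patch_speed_um_min=(-0.5, -0.5),
            noise_gaussian_sd=0.0, poisson_gain=0.0, jitter_max_px=0,
        )
        movie, truth = simulate_patch_movie(cfg)
        conv = movie.single("converted")
        with pytest.raises(ValueError, match="multiple patches"):
            track_patch(conv, truth.paths[0])
        t1 = track_patch(conv, truth.paths[0], start_um=8.0)
        t2 = track_patch(conv, truth.paths[0], start_um=22.0)
        assert abs(t1.arclen_um[0] - 8.0) < 1.0
        assert abs(t2.arclen_um[0] - 22.0) < 1.0

    def test_empty_corridor_raises(self):
        from neuroflow import MovieStack, NeuritePath

        movie = MovieStack(np.zeros((3, 40, 40)), 0.22, 30.0)
        path = NeuritePath(
            np.column_stack([np.full(30, 20.0), 5.0 + np.arange(30.0)]), 0.22
        )
        with pytest.raises(ValueError, match="no patch signal"):
            track_patch(movie, path)


class TestSpeedFromTrack:
    def test_retrograde_speed_and_direction(self):
        m = speed_from_track(_track(np.linspace(15.0, 10.0, 21)))  # 5 um in 10 min
        assert m.speed_um_min == pytest.approx(0.5)
        assert m.direction == "retrograde"

    def test_zero_displacement_is_immobile(self):
        m = speed_from_track(_track(np.full(21, 10.0)))
        assert m.direction == "immobile"
        assert m.speed_um_min == 0.0

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            speed_from_track(_track([10.0, 10.5, 11.0]))  # 1 min total

    def test_time_reversal_antisymmetry(self):
        tr = _track(np.linspace(15.0, 9.0, 15))
        fwd = speed_from_track(tr)
        rev = speed_from_track(tr.reversed())
        assert rev.speed_um_min == pytest.approx(fwd.speed_um_min)
        assert {fwd.direction, rev.direction} == {"retrograde", "anterograde"}

    def test_noisy_recovery_of_printed_drift(self, noisy_jittered_movie):
        from neuroflow import RegistrationConfig, register_movie

        cfg, movie, truth = noisy_jittered_movie
        registered, _ = register_movie(movie, RegistrationConfig(channel="tubulin"))
        tr = track_patch(
            registered.single("converted"), truth.paths[0], start_um=14.0
        )
        m = speed_from_track(tr)
        assert m.direction == "retrograde"
        assert m.speed_um_min == pytest.approx(0.53, abs=0.05)

    def test_point_track_with_soma_reference(self):
        pts = np.column_stack([np.full(11, 10.0), np.linspace(40.0, 30.0, 11)])
        tr = Track(frames=np.arange(11), points=pts, frame_interval_s=30.0)
        m = speed_from_track(tr, soma_point=np.array([10.0, 0.0]))
        assert m.direction == "retrograde"
        assert m.speed_um_min == pytest.approx(2.0)  # 10 px over 5 min


class TestPatchSynchrony:
    @pytest.mark.parametrize(
        "dists,expected",
        [((5.0, 4.0), 0.25), ((4.0, 4.0), 0.0), ((6.0, 5.0, 4.0), 0.5)],
    )
    def test_relative_distance_difference(self, dists, expected):
        tracks = [_track(np.linspace(15.0, 15.0 - d, 11)) for d in dists]
        assert patch_synchrony(tracks) == pytest.approx(expected)

    def test_zero_minimum_distance_undefined(self):
        tracks = [_track(np.full(11, 15.0)), _track(np.linspace(15, 10, 11))]
        assert np.isnan(patch_synchrony(tracks))


class TestCamsapTraces:
    def test_single_ridge_exact_slope(self):
        n, cols = 10, 80
        data = np.zeros((n, cols))
        for t in range(n):
            data[t, 60 - 2 * t] = 10.0
        kymo = Kymograph(data, 0.22, 30.0)
        traces = extract_camsap_traces(kymo, threshold=5.0)
        assert len(traces) == 1
        v = traces[0].speed_um_min(0.22, 30.0)
        assert v == pytest.approx(2 * 0.22 / 0.5)  # 2 px per 30 s, retrograde

    def test_two_parallel_ridges(self):
        data = np.zeros((8, 80))
        for t in range(8):
            data[t, 50 - t] = 10.0
            data[t, 60 - t] = 10.0
        traces = extract_camsap_traces(Kymograph(data, 0.22, 30.0), threshold=5.0)
        assert len(traces) == 2

    def test_empty_kymograph_no_traces(self):
        traces = extract_camsap_traces(Kymograph(np.zeros((5, 40)), 0.22, 30.0), threshold=1.0)
        assert traces == []

    def test_median_flow_discards_anterograde(self):
        mk = lambda p0, p1: KymoTrace([0, 5], [p0, p1])
        px, dt = 0.22, 60.0
        # slopes in um/min: 0.3 retro, 0.5 retro, 0.2 antero
        traces = [
            mk(50, 50 - 0.3 * 5 / px),
            mk(50, 50 - 0.5 * 5 / px),
            mk(50, 50 + 0.2 * 5 / px),
        ]
        series = camsap_flow_series(traces, px, dt, 6)
        assert np.allclose(series, 0.4)

    def test_uncovered_frames_missing(self):
        series = camsap_flow_series([KymoTrace([2, 4], [30, 20])], 0.22, 60.0, 8)
        assert np.isnan(series[0]) and np.isnan(series[-1])
        assert np.isfinite(series[3])

    def test_simulated_movie_median_speed(self):
        cfg = SimConfig(
            seed=9, n_neurites=1, camsap_n_puncta=4, camsap_speed_um_min=-0.4,
            n_frames=20, noise_gaussian_sd=0.0, jitter_max_px=0,
        )
        movie, truth = simulate_camsap_movie(cfg)
        kymo = sample_kymograph(movie, truth.paths[0], 11)
        traces = extract_camsap_traces(kymo, threshold=np.percentile(kymo.data, 96))
        series = camsap_flow_series(traces, cfg.pixel_size_um, cfg.frame_interval_s, cfg.n_frames)
        assert np.nanmedian(series) == pytest.approx(0.4, abs=0.08)


class TestDetectSlowdown:
    def _flows(self, axon, others, n=400):
        flows = {0: np.full(n, axon)}
        for i, v in enumerate(others, start=1):
            flows[i] = np.full(n, v)
        return flows

    def test_halved_axon_detected_at_onset_zero(self):
        res = detect_slowdown(self._flows(0.25, [0.5, 0.6]), 0, frame_interval_s=60.0)
        assert res.detected and res.onset_min == 0.0

    def test_equal_flow_not_detected(self):
        res = detect_slowdown(self._flows(0.5, [0.5, 0.5]), 0, frame_interval_s=60.0)
        assert not res.detected and res.evaluable

    def test_short_span_not_evaluable(self):
        res = detect_slowdown(self._flows(0.2, [0.5], n=100), 0, frame_interval_s=60.0)
        assert not res.evaluable

    def test_step_slowdown_onset_within_smoothing_window(self):
        n, t0 = 420, 150
        axon = np.concatenate([np.full(t0, 0.5), np.full(n - t0, 0.2)])
        flows = {0: axon, 1: np.full(n, 0.5), 2: np.full(n, 0.55)}
        res = detect_slowdown(flows, 0, frame_interval_s=60.0)
        assert res.detected
        assert abs(res.onset_min - t0) <= 200.0

    def test_scale_invariance(self):
        flows = self._flows(0.3, [0.5, 0.7])
        r1 = detect_slowdown(flows, 0, frame_interval_s=60.0)
        r2 = detect_slowdown({k: 7.3 * v for k, v in flows.items()}, 0, frame_interval_s=60.0)
        assert (r1.detected, r1.onset_min) == (r2.detected, r2.onset_min)


class TestClassifyAxon:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([60.0, 20.0, 15.0], "with_axon"),
            ([25.0, 20.0], "no_axon"),
            ([35.0, 28.0], "transition"),
            ([55.0, 50.0], "transition"),  # long but not 10 um ahead
            ([45.0, 20.0], "transition"),
        ],
    )
    def test_rules(self, lengths, expected):
        assert classify_axon(lengths) == expected

    def test_needs_two_neurites(self):
        with pytest.raises(ValueError):
            classify_axon([40.0])


class TestNeuriteBackground:
    def test_constant_cells(self):
        kymo = Kymograph(np.full((10, 40), 7.0), 0.22, 30.0)
        assert neurite_background(kymo) == 7.0

    def test_floored_at_previous_maximum(self):
        kymo = Kymograph(np.full((10, 40), 5.0), 0.22, 30.0)
        assert neurite_background(kymo, previous_backgrounds=(7.0, 3.0)) == 7.0

    def test_equals_brute_force_min_over_stated_cells(self, rng):
        data = rng.uniform(0, 100, (12, 50))
        kymo = Kymograph(data, 0.22, 30.0)
        cells = np.concatenate([data[0, :5], data[-4:, :5].ravel()])
        assert neurite_background(kymo) == cells.min()


class TestPatchSpread:
    def test_symmetric_profile_symmetric_speeds(self):
        prof = np.concatenate([np.arange(1.0, 11.0), np.arange(9.0, 0.0, -1.0)])
        data = np.tile(np.concatenate([np.zeros(5), prof, np.zeros(5)]), (5, 1)) + 5.0
        kymo = Kymograph(data, 0.22, 30.0)
        res = patch_spread(kymo, start_px=14, background=5.0)
        assert res.retro_speed_um_min == pytest.approx(res.antero_speed_um_min)
        assert np.ptp(res.spread_um) == 0.0

    def test_ten_equal_pixels_remove_exactly_one(self):
        data = np.zeros((2, 30))
        data[:, 10:20] = 1.0
        res = patch_spread(Kymograph(data, 0.22, 30.0), start_px=14, background=0.0)
        assert res.spread_um[0] == pytest.approx(8 * 0.22)

    def test_below_threshold_first_row_raises(self):
        kymo = Kymograph(np.full((3, 20), 1.0), 0.22, 30.0)
        with pytest.raises(ValueError):
            patch_spread(kymo, start_px=10, background=1.0)

    def test_drifting_spreading_patch_retro_faster(self):
        # patch drifts retrogradely while spreading: retro edge speed higher
        px, n = 0.22, 8
        cols = np.arange(120)
        data = np.zeros((n, 120))
        for t in range(n):
            center = 60 - 1.5 * t
            sigma = 3.0 + 0.5 * t
            data[t] = 50.0 * np.exp(-0.5 * ((cols - center) / sigma) ** 2)
        kymo = Kymograph(data + 2.0, px, 30.0)
        res = patch_spread(kymo, start_px=60, background=2.0)
        assert res.retro_speed_um_min > res.antero_speed_um_min


class TestMassDistribution:
    def test_all_mass_retrograde(self):
        data = np.zeros((4, 100))
        data[:, 10:20] = 5.0
        kymo = Kymograph(data, 0.22, 30.0)
        f = mass_distribution(kymo, start_px=60, background=0.0)
        assert f == pytest.approx((1.0, 0.0, 0.0))

    def test_point_mass_at_start_is_stationary(self):
        data = np.zeros((4, 100))
        data[:, 60] = 5.0
        f = mass_distribution(Kymograph(data, 0.22, 30.0), start_px=60, background=0.0)
        assert f == pytest.approx((0.0, 1.0, 0.0))

    def test_fractions_sum_to_one_and_background_invariant(self):
        cfg = SimConfig(seed=17, n_frames=10)
        kymo, truth = simulate_mass_kymograph(cfg, (0.5, 0.2, 0.3))
        f1 = mass_distribution(kymo, start_px=truth.mass_start_px)
        assert sum(f1) == pytest.approx(1.0, abs=1e-9)
        shifted = Kymograph(
            kymo.data + 13.0, kymo.pixel_size_um, kymo.frame_interval_s
        )
        f2 = mass_distribution(shifted, start_px=truth.mass_start_px)
        assert np.allclose(f1, f2, atol=1e-9)

    def test_recovers_simulated_partition(self):
        cfg = SimConfig(seed=8, n_frames=12)
        kymo, truth = simulate_mass_kymograph(cfg, (0.84, 0.06, 0.10))
        f = mass_distribution(kymo, start_px=truth.mass_start_px)
        assert np.allclose(f, (0.84, 0.06, 0.10), atol=0.03)

    def test_zero_mass_undefined(self):
        kymo = Kymograph(np.full((3, 40), 2.0), 0.22, 30.0)
        with pytest.raises(ValueError):
            mass_distribution(kymo, start_px=20, background=2.0)


class TestParameterRecoverySweep:
    def test_drift_sweep_mean_error_bounded(self):
        # 30 seeded simulations across 0.2-1.0 um/min; mean absolute error
        # of the recovered drift <= 0.05 um/min (no jitter: isolates the
        # tracking estimator)
        from neuroflow import speed_from_track

        drifts = np.linspace(0.2, 1.0, 30)
        errs = []
        for i, d in enumerate(drifts):
            cfg = SimConfig(
                seed=3000 + i, patch_speed_um_min=(-d,), jitter_max_px=0,
                noise_gaussian_sd=15.0, poisson_gain=1.0, bleach_rate_per_min=0.02,
            )
            movie, truth = simulate_patch_movie(cfg)
            tr = track_patch(movie.single("converted"), truth.paths[0], start_um=14.0)
            errs.append(abs(speed_from_track(tr).speed_um_min - d))
        assert np.mean(errs) <= 0.05
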