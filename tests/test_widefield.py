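"""Quiet-wakefulness gating and per-pixel event detection/metrics."""

import numpy as np
import pytest

from glioscope import synth, widefield
from glioscope.core import ActivityMovie


def make_movie(dff, frame_rate=10.0, pixel_size=36.0):
    return ActivityMovie(dff=dff, frame_rate=frame_rate, pixel_size=pixel_size)


class TestDownsample:
    def test_uniform_movie_unchanged_pixel_size_scaled(self):
        movie = make_movie(np.full((5, 16, 16), 2.0), pixel_size=36.0)
        out = widefield.downsample_movie(movie, factor=8)
        assert out.pixel_size == pytest.approx(288.0)
        np.testing.assert_allclose(out.dff, 2.0)

    def test_single_bright_pixel_block_mean(self):
        dff = np.zeros((1, 8, 8)); dff[0, 3, 3] = 64.0
        out = widefield.downsample_movie(make_movie(dff), factor=8)
        assert out.dff[0, 0, 0] == pytest.approx(1.0)

    def test_edges_trimmed_and_mask_majority(self):
        movie = ActivityMovie(dff=np.zeros((2, 17, 18)), frame_rate=10,
                              pixel_size=36,
                              valid_mask=np.ones((17, 18), dtype=bool))
        movie.valid_mask[:, :9] = False
        out = widefield.downsample_movie(movie, factor=8)
        assert out.dff.shape == (2, 2, 2)
        assert not out.valid_mask[0, 0] and out.valid_mask[0, 1]

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            widefield.downsample_movie(make_movie(np.zeros((1, 8, 8))), factor=0)


class TestQuietEpochs:
    def behavior(self, run_bouts=(), whisk_bouts=(), duration=400.0, fs=10.0,
                 seed=0):
        return synth.generate_behavior(synth.BehaviorSpec(
            duration_s=duration, sample_rate_hz=fs,
            run_bouts=list(run_bouts), whisk_bouts=list(whisk_bouts), seed=seed))

    def test_still_recording_is_fully_quiet(self):
        q = widefield.detect_quiet_epochs(self.behavior())
        assert q.quiet.all() and q.sufficient
        assert q.total_quiet_s == pytest.approx(400.0)

    def test_run_bout_above_threshold_excluded(self):
        q = widefield.detect_quiet_epochs(self.behavior(run_bouts=[(50, 70, 0.05)]))
        t = np.arange(len(q.quiet)) / 10.0
        assert not q.quiet[(t >= 50) & (t < 70)].any()
        assert q.quiet[t < 50].all()

    def test_slow_locomotion_below_threshold_kept(self):
        q = widefield.detect_quiet_epochs(self.behavior(run_bouts=[(50, 70, 0.04)]))
        assert q.quiet.all()

    def test_whisk_bout_excluded(self):
        q = widefield.detect_quiet_epochs(
            self.behavior(whisk_bouts=[(100, 130, 1.0)], seed=3))
        t = np.arange(len(q.quiet)) / 10.0
        inside = q.quiet[(t >= 101) & (t < 129)]
        assert inside.mean() < 0.05
        assert q.quiet[t < 99].mean() > 0.95

    def test_selected_frames_are_earliest(self):
        q = widefield.detect_quiet_epochs(self.behavior(duration=400.0))
        assert q.selected.sum() == 3000
        assert q.selected[:3000].all() and not q.selected[3000:].any()

    def test_insufficient_quiet_flagged_and_raises_downstream(self):
        q = widefield.detect_quiet_epochs(
            self.behavior(run_bouts=[(0, 250, 0.05)], duration=400.0))
        assert not q.sufficient
        movie = make_movie(np.zeros((4000, 2, 2)))
        with pytest.raises(widefield.InsufficientQuietError):
            widefield.compute_pixel_metrics(movie, q)


class TestEventDetection:
    def test_rectangular_pulse_recovered_exactly(self):
        trace = np.zeros(300)
        trace[100:110] = 5.0
        events = widefield.detect_pixel_events(trace, frame_rate=10.0)
        assert len(events) == 1
        e = events.iloc[0]
        assert (e.onset, e.offset) == (100, 109)
        assert e.duration_s == pytest.approx(1.0)
        assert e.peak == pytest.approx(5.0)

    def test_constant_trace_has_no_events(self):
        assert len(widefield.detect_pixel_events(np.ones(500), 10.0)) == 0

    def test_pure_noise_run_count_matches_monte_carlo_oracle(self):
        """Detected counts on pure noise match an independent simulation of the
        detection rule (smoothed Gaussian runs of >= 2 frames above median+3SD)."""
        rng = np.random.default_rng(0)
        fs, t_len, w = 10.0, 3000, 5
        # oracle: direct Monte-Carlo of the thresholding rule with known sigma
        oracle_counts = []
        for _ in range(100):
            x = rng.normal(0, 1, t_len)
            sm = np.convolve(x, np.ones(w) / w, mode="same")
            above = sm > np.median(x) + 3.0
            padded = np.diff(np.concatenate([[0], above.astype(int), [0]]))
            runs = np.flatnonzero(padded == 1)
            ends = np.flatnonzero(padded == -1)
            oracle_counts.append(int(np.sum((ends - runs) >= 2)))
        detected = []
        for seed in range(100):
            x = np.random.default_rng(1000 + seed).normal(0, 1, t_len)
            detected.append(len(widefield.detect_pixel_events(x, fs)))
        se = np.std(oracle_counts) / 10 + np.std(detected) / 10 + 0.05
        assert abs(np.mean(detected) - np.mean(oracle_counts)) < 3 * se

    def test_rate_monotone_nonincreasing_in_threshold(self):
        """Higher k means fewer events (on non-overlapping transients, whose
        count is unambiguous)."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            trace = r.normal(0, 1, 2000)
            for i, t0 in enumerate(range(100, 1900, 150)):
                trace[t0:t0 + 10] += r.uniform(3, 8)
            counts = [len(widefield.detect_pixel_events(trace, 10.0, k=k))
                      for k in (2.0, 2.5, 3.0, 4.0, 5.0)]
            assert counts == sorted(counts, reverse=True)

    def test_overlapping_transients_are_split(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(0, 1, 600)
        trace[100:110] += 5.0
        trace[106:116] += 5.0
        events = widefield.detect_pixel_events(trace, 10.0)
        assert len(events) == 2


class TestPixelMetrics:
    def test_zero_movie_zero_metrics(self):
        movie = make_movie(np.zeros((500, 3, 3)))
        pm = widefield.compute_pixel_metrics(movie)
        np.testing.assert_allclose(pm.activity_per_min, 0.0)
        np.testing.assert_allclose(pm.events_per_sec, 0.0)
        assert len(pm.events) == 0

    def test_rate_arithmetic(self):
        """30 planted events in 300 s of quiet -> 0.1 events/s."""
        fs = 10.0
        trace = np.zeros(3000)
        rng = np.random.default_rng(0)
        onsets = np.arange(30) * 99 + 5
        noise = rng.normal(0, 0.3, 3000)
        for t0 in onsets:
            trace[t0:t0 + 8] += 5.0
        movie = make_movie((trace + noise).reshape(-1, 1, 1), frame_rate=fs)
        pm = widefield.compute_pixel_metrics(movie)
        assert pm.events_per_sec[0, 0] == pytest.approx(0.1, abs=0.005)

    def test_metrics_nan_outside_valid_mask(self):
        movie = ActivityMovie(dff=np.zeros((500, 2, 2)), frame_rate=10,
                              pixel_size=36,
                              valid_mask=np.array([[True, False],
                                                   [True, True]]))
        pm = widefield.compute_pixel_metrics(movie)
        assert np.isnan(pm.activity_per_min[0, 1])
        assert np.isfinite(pm.activity_per_min[0, 0])

    def test_activity_invariant_to_frame_permutation_durations_not(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 1, 2000)
        for t0 in (100, 500, 900, 1400):
            trace[t0:t0 + 12] += 6.0
        perm = rng.permutation(2000)
        m1 = widefield.compute_pixel_metrics(make_movie(trace.reshape(-1, 1, 1)))
        m2 = widefield.compute_pixel_metrics(
            make_movie(trace[perm].reshape(-1, 1, 1)))
        assert m1.activity_per_min[0, 0] == pytest.approx(m2.activity_per_min[0, 0],
                                                          rel=1e-6)
        assert m1.mean_duration[0, 0] != m2.mean_duration[0, 0]

    def test_random_movie_specs_recover_all_metrics(self):
        """Median relative recovery error of all four metrics stays below 10%
        across a spread of planted rates, amplitudes and durations."""
        rng = np.random.default_rng(42)
        errs = {name: [] for name in widefield.METRIC_NAMES}
        for i in range(8):
            spec = synth.MovieSpec(
                duration_s=150.0, frame_rate_hz=10.0, fov_shape=(12, 12),
                pixel_size=240.0, baseline_noise_sd=1.0,
                event_rate=float(rng.uniform(0.05, 0.15)),
                amplitude=float(rng.uniform(4.5, 8.0)),
                event_duration_s=float(rng.uniform(0.8, 1.6)),
                seed=int(rng.integers(2 ** 31)))
            movie, catalog, truth = synth.generate_movie(spec)
            pm = widefield.compute_pixel_metrics(movie)
            n_px = spec.fov_shape[0] * spec.fov_shape[1]
            targets = {
                "activity_per_min": truth["mean_signal"] * 600.0,
                "events_per_sec": np.full(spec.fov_shape,
                                          len(catalog) / n_px / 150.0),
                "mean_amplitude": truth["amplitude_map"],
                "mean_duration": np.full(spec.fov_shape, truth["duration_s"]),
            }
            for name in errs:
                rel = (pm.metric(name) - targets[name]) / targets[name]
                errs[name].append(np.nanmedian(rel))
        for name, vals in errs.items():
            assert abs(np.median(vals)) < 0.10, (name, vals)
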