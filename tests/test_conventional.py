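"""Despiking, smoothing, Hilbert-envelope episode detection and baselines."""

import numpy as np
import pytest
from scipy.signal import hilbert

from ctgnet.conventional import (
    detect_episodes,
    extract_features,
    fit_kmeans,
    fit_svm,
    predict_kmeans,
    predict_svm,
    remove_spikes,
    smooth,
)
from ctgnet.synthetic import TraceGenParams, generate_trace


class TestRemoveSpikes:
    def test_clean_series_identity(self):
        x = 140.0 + np.sin(np.arange(100) / 10.0)
        np.testing.assert_array_equal(remove_spikes(x), x)

    def test_out_of_range_sample_replaced_by_neighbor_mean(self):
        out = remove_spikes(np.array([140.0, 140.0, 300.0, 140.0]))
        np.testing.assert_allclose(out, 140.0)

    def test_two_sample_spike_removed(self):
        x = 140.0 + np.sin(np.arange(200) / 20.0) * 5
        spiked = x.copy()
        spiked[100:102] += 80.0
        out = remove_spikes(spiked)
        np.testing.assert_allclose(out, x, atol=1.0)

    def test_leading_flagged_run_takes_nearest_value(self):
        out = remove_spikes(np.array([300.0, 300.0, 140.0, 141.0]))
        np.testing.assert_allclose(out[:2], 140.0)

    def test_all_flagged_raises(self):
        with pytest.raises(ValueError, match="every sample"):
            remove_spikes(np.array([300.0, 301.0, 302.0]))


class TestSmooth:
    def test_constant_identity(self):
        np.testing.assert_allclose(smooth(np.full(50, 7.0)), 7.0)

    def test_interior_impulse_spreads_to_one_fifteenth(self):
        x = np.zeros(61)
        x[30] = 1.0
        out = smooth(x)
        np.testing.assert_allclose(out[24:37], 1.0 / 15.0)
        assert out[22] == 0.0

    def test_white_noise_variance_reduced_by_window(self, rng):
        draws = rng.normal(0.0, 1.0, (1000, 101))
        sm = np.array([smooth(d) for d in draws])
        interior_var = sm[:, 50].var()
        assert interior_var == pytest.approx(1.0 / 15.0, rel=0.15)

    def test_linear_and_shift_equivariant_interior(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0, 1, 80)
        lhs = smooth(2 * a + 3 * b)
        rhs = 2 * smooth(a) + 3 * smooth(b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth(np.ones(10))


class TestDetectEpisodes:
    def test_sinusoid_envelope_is_constant(self):
        # |analytic signal| of A*sin(2*pi*f*t) is A away from the edges
        t = np.arange(2000)
        d = 20.0 * np.sin(2 * np.pi * t / 120.0)
        env = np.abs(hilbert(d))
        np.testing.assert_allclose(env[200:-200], 20.0, rtol=0.05)

    def test_flat_trace_gives_no_episodes(self):
        assert detect_episodes(np.full(1800, 140.0)) == []

    def test_single_planted_deceleration_recovered(self):
        t = np.arange(1800, dtype=float)
        onset, dur, depth = 900.0, 60.0, -30.0
        pulse = np.zeros(1800)
        inside = (t >= onset) & (t <= onset + dur)
        pulse[inside] = depth * 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - onset) / dur))
        episodes = detect_episodes(smooth(140.0 + pulse))
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.kind == "deceleration"
        assert abs(ep.onset_s - onset) <= 5.0
        assert abs(ep.offset_s - (onset + dur)) <= 5.0
        assert ep.area_bpm_s == pytest.approx(abs(depth) * dur / 2.0, rel=0.15)

    def test_planted_recall_on_noiseless_traces(self, noiseless_params):
        n_planted = n_found = 0
        for seed in range(8):
            for label in ("normal", "abnormal"):
                tr, eps = generate_trace(
                    noiseless_params, label, np.random.default_rng(1000 + seed)
                )
                det = detect_episodes(smooth(tr.fhr))
                for ep in eps:
                    if abs(ep.depth_bpm) < 20:
                        continue
                    n_planted += 1
                    hits = [
                        d
                        for d in det
                        if abs(d.onset_s - ep.onset_s) <= 5
                        and abs(d.offset_s - ep.offset_s) <= 5
                        and (d.kind == "acceleration") == (ep.depth_bpm > 0)
                    ]
                    n_found += len(hits) > 0
        assert n_planted > 20
        assert n_found / n_planted >= 0.9

    def test_recall_with_moderate_variability(self):
        # overlap-based recovery at variability amplitude 5 bpm
        params = TraceGenParams(variability_amp_bpm=5.0, dropout_fraction=0.0, fs=1.0)
        n_planted = n_found = 0
        for seed in range(8):
            for label in ("normal", "abnormal"):
                tr, eps = generate_trace(params, label, np.random.default_rng(2000 + seed))
                det = detect_episodes(smooth(tr.fhr))
                for ep in eps:
                    if abs(ep.depth_bpm) < 20:
                        continue
                    n_planted += 1
                    mid = 0.5 * (ep.onset_s + ep.offset_s)
                    n_found += any(
                        d.onset_s <= mid <= d.offset_s
                        and (d.kind == "acceleration") == (ep.depth_bpm > 0)
                        for d in det
                    )
        assert n_found / n_planted >= 0.9

    def test_features_invariant_to_baseline_offset(self, noiseless_params):
        tr, _ = generate_trace(noiseless_params, "abnormal", np.random.default_rng(5))
        f0 = extract_features(detect_episodes(smooth(tr.fhr)))
        f1 = extract_features(detect_episodes(smooth(tr.fhr + 12.0)))
        assert f0.n_accelerations == f1.n_accelerations
        assert f0.total_decel_area == pytest.approx(f1.total_decel_area, rel=0.02)


class TestExtractFeatures:
    def test_empty(self):
        fv = extract_features([])
        assert fv.n_accelerations == 0 and fv.total_decel_area == 0.0

    def test_aggregation(self):
        from ctgnet.conventional import Episode

        eps = [
            Episode("acceleration", 0, 20, 20.0, 200.0),
            Episode("acceleration", 50, 70, 18.0, 180.0),
            Episode("deceleration", 100, 160, -30.0, 1800.0),
        ]
        fv = extract_features(eps)
        assert fv.n_accelerations == 2
        assert fv.total_decel_area == pytest.approx(1800.0)

    def test_detection_plus_integration_against_ground_truth(self, noiseless_params):
        tr, eps = generate_trace(noiseless_params, "abnormal", np.random.default_rng(77))
        fv = extract_features(detect_episodes(smooth(tr.fhr)))
        true_area = sum(e.area_bpm_s for e in eps if e.depth_bpm < 0)
        assert fv.total_decel_area == pytest.approx(true_area, rel=0.15)


class TestSVM:
    def _toy(self, rng, n=40):
        X = np.vstack(
            [
                np.column_stack([rng.normal(5, 0.3, n), rng.normal(0, 30, n)]),
                np.column_stack([rng.normal(0, 0.3, n), rng.normal(3000, 30, n)]),
            ]
        )
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_separable_training_accuracy(self, rng):
        X, y = self._toy(rng)
        model = fit_svm(X, y)
        assert (predict_svm(model, X) == y).mean() == 1.0

    def test_interior_point_classified(self, rng):
        X, y = self._toy(rng)
        model = fit_svm(X, y)
        assert predict_svm(model, np.array([[0.0, 3000.0]]))[0] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_svm(np.ones((5, 2)), np.ones(5))


class TestKMeans:
    def test_separated_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        model = fit_kmeans(X, y, seed=0)
        assert (predict_kmeans(model, X) == y).mean() == 1.0

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_kmeans(np.ones((10, 2)), np.r_[np.zeros(5), np.ones(5)])

    def test_fixed_seed_deterministic(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = (X[:, 0] > 0).astype(int)
        a = fit_kmeans(X, y, seed=3)
        b = fit_kmeans(X, y, seed=3)
        np.testing.assert_array_equal(predict_kmeans(a, X), predict_kmeans(b, X))

    def test_overlapping_blobs_near_nearest_centroid_oracle(self, rng):
        X = np.vstack([rng.normal(0, 1.0, (100, 2)), rng.normal(2.5, 1.0, (100, 2))])
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        model = fit_kmeans(X, y, seed=1)
        acc = (predict_kmeans(model, X) == y).mean()
        # brute-force nearest-centroid assignment using the true class means
        mu = np.array([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        d = ((X[:, None, :] - mu[None]) ** 2).sum(axis=2)
        bayes = (np.argmin(d, axis=1) == y).mean()
        assert abs(acc - bayes) <= 0.05
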