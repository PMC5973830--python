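"""Shrinkage LDA, class balancing, and cross-validated time-resolved decoding."""

import numpy as np
import pytest
from scipy import stats as sp_stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from tgdecode import (
    SimulationConfig,
    TemporalDecoder,
    TimeWindow,
    balance_classes,
    decode_diagonal,
    decode_eyetrack,
    decode_generalization,
    fit_lda,
    oracle_accuracy,
    simulate_subject,
)


def gaussian_classes(rng, n_per_class, n_features, d):
    """Two Gaussian classes separated by Mahalanobis distance d (identity cov)."""
    y = rng.permutation(np.repeat([0, 1], n_per_class))
    X = rng.standard_normal((2 * n_per_class, n_features))
    X[:, 0] += np.where(y == 1, d / 2, -d / 2)
    return X, y


class TestFitLDA:
    def test_separable_1d_training_accuracy(self):
        X = np.array([[-1.0], [-1.001], [-0.999], [1.0], [1.001], [0.999]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_lda(X, y, shrinkage=0.0)
        assert (model.predict(X) == y).all()

    def test_identical_means_near_chance(self, rng):
        X, y = gaussian_classes(rng, 300, 10, d=0.0)
        Xte, yte = gaussian_classes(rng, 300, 10, d=0.0)
        model = fit_lda(X, y)
        acc = (model.predict(Xte) == yte).mean()
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 600)

    def test_heldout_accuracy_approaches_oracle(self, rng):
        d = 2.0
        X, y = gaussian_classes(rng, 600, 15, d=d)
        Xte, yte = gaussian_classes(rng, 600, 15, d=d)
        model = fit_lda(X, y)
        acc = (model.predict(Xte) == yte).mean()
        assert acc == pytest.approx(oracle_accuracy([d] + [0] * 14, np.eye(15)),
                                    abs=0.03)

    def test_matches_sklearn_at_fixed_shrinkage(self, rng):
        X, y = gaussian_classes(rng, 60, 20, d=1.5)
        Xte, yte = gaussian_classes(rng, 200, 20, d=1.5)
        gamma = 0.3
        ours = fit_lda(X, y, shrinkage=gamma)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma).fit(X, y)
        agreement = (ours.predict(Xte) == ref.predict(Xte)).mean()
        assert agreement >= 0.97

    def test_auto_shrinkage_tracks_ledoit_wolf(self, rng):
        from sklearn.covariance import ledoit_wolf_shrinkage

        X, y = gaussian_classes(rng, 40, 25, d=1.0)
        model = fit_lda(X, y)
        resid = X.copy()
        for c in (0, 1):
            resid[y == c] -= X[y == c].mean(axis=0)
        expected = ledoit_wolf_shrinkage(resid, assume_centered=True)
        assert model.shrinkage == pytest.approx(expected, abs=0.05)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_lda(np.random.default_rng(0).standard_normal((8, 3)), np.zeros(8))

    def test_rejects_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_lda(np.ones((8, 3)), np.arange(8) % 2)


class TestBalanceClasses:
    def test_already_balanced_is_identity(self):
        y = np.arange(20) % 2
        np.testing.assert_array_equal(balance_classes(y, 0), np.arange(20))

    def test_majority_trimmed_to_minority(self):
        y = np.array([0] * 12 + [1] * 10)
        kept = balance_classes(y, 3)
        assert (y[kept] == 0).sum() == 10 and (y[kept] == 1).sum() == 10

    def test_deterministic_under_seed(self):
        y = np.array([0] * 15 + [1] * 9)
        np.testing.assert_array_equal(balance_classes(y, 7), balance_classes(y, 7))

    def test_removed_trials_vary_with_seed(self):
        y = np.array([0] * 30 + [1] * 10)
        assert not np.array_equal(balance_classes(y, 1), balance_classes(y, 2))


def _subject(scenario="sustained", seed=3, **kw):
    base = dict(n_sensors=16, fs=100.0, n_trials_per_class=30,
                epoch_window=TimeWindow(-0.1, 0.6), snr=0.8)
    base.update(kw)
    cfg = SimulationConfig(scenario=scenario, **base)
    return simulate_subject(cfg, seed), cfg


class TestDecodeDiagonal:
    def test_null_subject_stays_at_chance(self):
        subj, _ = _subject("null")
        tc = decode_diagonal(subj.perception, seed=0)
        # 60 trials, 60 time points: grand mean within 3 SE of binomial chance
        se = np.sqrt(0.25 / 60) / np.sqrt(tc.accuracy.size / 3)  # ~3-sample smoothing
        assert abs(tc.accuracy.mean() - 0.5) < 3 * se

    def test_high_snr_window_is_decodable(self):
        subj, cfg = _subject("sustained", snr=1.5)
        tc = decode_diagonal(subj.perception, seed=0)
        w = cfg.pattern_times[0]
        inside = w.mask(tc.times)
        assert tc.accuracy[inside].mean() > 0.9
        before = tc.times < 0.0
        assert abs(tc.accuracy[before].mean() - 0.5) < 0.12

    def test_deterministic_under_seed(self):
        subj, _ = _subject()
        a = decode_diagonal(subj.perception, seed=5)
        b = decode_diagonal(subj.perception, seed=5)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)

    def test_test_folds_cover_all_trials_once(self):
        # 5 folds of 100 trials: each fold tests 20, pooled denominator is 100
        subj, _ = _subject(n_trials_per_class=50)
        from tgdecode.decoding import _stratified_folds

        folds = _stratified_folds(subj.perception.labels, 5, seed=0)
        sizes = [len(te) for _, te in folds]
        assert sizes == [20] * 5
        covered = np.sort(np.concatenate([te for _, te in folds]))
        np.testing.assert_array_equal(covered, np.arange(100))

    def test_rejects_too_few_trials(self):
        subj, _ = _subject(n_trials_per_class=4)
        with pytest.raises(ValueError):
            decode_diagonal(subj.perception, k_folds=5)


class TestGeneralization:
    def test_diagonal_equals_dedicated_timecourse(self):
        subj, _ = _subject()
        mat = decode_generalization(subj.perception, seed=9)
        tc = decode_diagonal(subj.perception, seed=9)
        np.testing.assert_array_equal(mat.diagonal(), tc.accuracy)

    def test_sequential_patterns_do_not_cross_generalize(self):
        subj, cfg = _subject("sequential", n_patterns=2, snr=1.5,
                             n_trials_per_class=50)
        mat = decode_generalization(subj.perception, seed=0)
        w1, w2 = cfg.pattern_times
        t = mat.train_times
        core1 = (t >= w1.start_s + 0.1) & (t < w1.end_s - 0.1)
        core2 = (t >= w2.start_s + 0.1) & (t < w2.end_s - 0.1)
        same = mat.accuracy[np.ix_(core1, core1)].mean()
        cross = mat.accuracy[np.ix_(core1, core2)].mean()
        assert same > 0.8
        assert abs(cross - 0.5) < 0.1

    def test_cross_condition_requires_paired_trials(self):
        subj, _ = _subject()
        truncated = subj.imagery.copy_with(
            data=subj.imagery.data[:-2], labels=subj.imagery.labels[:-2])
        with pytest.raises(ValueError, match="paired"):
            decode_generalization(subj.perception, truncated)
        shuffled = subj.imagery.copy_with(labels=subj.imagery.labels[::-1].copy())
        with pytest.raises(ValueError, match="paired"):
            decode_generalization(subj.perception, shuffled)

    def test_cross_condition_transfers_shared_pattern(self):
        subj, cfg = _subject("sustained", snr=1.5, n_trials_per_class=50)
        mat = decode_generalization(subj.perception, subj.imagery, seed=1)
        assert mat.train_condition == "perception"
        assert mat.test_condition == "imagery"
        w = cfg.pattern_times[0]
        rows = w.mask(mat.train_times)
        cols = cfg.imagery_window.mask(mat.test_times)
        assert mat.accuracy[np.ix_(rows, cols)].mean() > 0.6

    def test_model_front_end_matches_functions(self):
        subj, _ = _subject()
        a = TemporalDecoder(subj.perception).fit(seed=4)
        b = decode_generalization(subj.perception, seed=4)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        tc = TemporalDecoder(subj.perception).fit_diagonal(seed=4)
        np.testing.assert_array_equal(tc.accuracy, np.diag(b.accuracy))


class TestEyetrack:
    def test_null_eye_channels_at_chance(self):
        subj, _ = _subject("sustained")
        tc = decode_eyetrack(subj, seed=0)
        assert abs(tc.accuracy.mean() - 0.5) < 0.1

    def test_gaze_offset_is_decodable(self):
        subj, cfg = _subject("sustained", eye_effect=1.5)
        tc = decode_eyetrack(subj, seed=0)
        inside = cfg.pattern_times[0].mask(tc.times)
        assert tc.accuracy[inside].mean() > 0.75

    def test_requires_two_channels(self):
        subj, _ = _subject()
        with pytest.raises(ValueError, match="2 channels"):
            decode_eyetrack(subj.perception)
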