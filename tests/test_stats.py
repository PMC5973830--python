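"""Cluster-mass permutation inference, temporal specificity, median splits
and correlation tests: calibration and recovery on constructed maps."""

import numpy as np
import pytest

from tgdecode import (
    cluster_permutation_two_groups,
    cluster_permutation_vs_chance,
    correlation_cluster_test,
    correlation_test,
    median_split_compare,
    specificity_index,
)


def block_maps(rng, n_subjects=25, n_points=50, lo=20, hi=30, effect=0.2, sd=0.02):
    maps = 0.5 + rng.normal(0, sd, (n_subjects, n_points))
    maps[:, lo:hi] += effect
    return maps


class TestVsChance:
    def test_exact_chance_maps_produce_no_clusters(self):
        res = cluster_permutation_vs_chance(np.full((10, 30), 0.5), 0.5,
                                            n_perm=200, seed=0)
        assert res.n_clusters == 0
        assert not res.mask().any()

    def test_block_effect_recovered_exactly(self, rng):
        res = cluster_permutation_vs_chance(block_maps(rng), 0.5, n_perm=1000, seed=1)
        sig = res.significant()
        assert len(sig) == 1
        members = res.clusters[sig[0]][:, 0]
        assert res.sign[sig[0]] == "positive"
        np.testing.assert_array_equal(np.sort(members), np.arange(20, 30))

    def test_2d_maps_use_4_connectivity(self, rng):
        maps = 0.5 + rng.normal(0, 0.02, (20, 12, 12))
        maps[:, 2:5, 2:5] += 0.2
        maps[:, 8:11, 8:11] += 0.2  # diagonal touch only -> two clusters
        res = cluster_permutation_vs_chance(maps, 0.5, n_perm=500, seed=2)
        pos = [i for i in res.significant() if res.sign[i] == "positive"]
        assert len(pos) == 2

    def test_p_values_never_zero(self, rng):
        res = cluster_permutation_vs_chance(block_maps(rng), 0.5, n_perm=300, seed=3)
        assert (res.p_value > 0).all()
        assert res.p_value.min() >= 1 / 301

    def test_invariant_to_common_shift_of_maps_and_chance(self, rng):
        maps = block_maps(rng)
        a = cluster_permutation_vs_chance(maps, 0.5, n_perm=300, seed=4)
        b = cluster_permutation_vs_chance(maps + 0.17, 0.67, n_perm=300, seed=4)
        np.testing.assert_allclose(a.p_value, b.p_value)
        np.testing.assert_allclose(a.mass, b.mass, rtol=1e-10)

    def test_matches_mne_observed_clusters(self, rng):
        mne_stats = pytest.importorskip("mne.stats")
        from scipy import stats as sp_stats

        maps = block_maps(rng, n_subjects=15, effect=0.05, sd=0.04)
        diffs = maps - 0.5
        thr = sp_stats.t.ppf(1 - 0.05 / 2, 14)
        _, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            diffs, threshold=thr, tail=1, n_permutations=100, seed=0,
            out_type="indices", verbose=False)
        ours = cluster_permutation_vs_chance(maps, 0.5, n_perm=100, seed=0)
        ours_pos = sorted(
            tuple(np.sort(c[:, 0])) for c, s in zip(ours.clusters, ours.sign)
            if s == "positive")
        mne_pos = sorted(tuple(np.sort(c[0])) for c in clusters)
        assert ours_pos == mne_pos

    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            cluster_permutation_vs_chance(np.zeros((1, 10)), 0.0)

    def test_warns_on_few_permutations(self, rng):
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_permutation_vs_chance(block_maps(rng), 0.5, n_perm=50, seed=0)

    def test_separate_tail_mode_available(self, rng):
        maps = block_maps(rng)
        joint = cluster_permutation_vs_chance(maps, 0.5, n_perm=400, seed=5)
        sep = cluster_permutation_vs_chance(maps, 0.5, n_perm=400, seed=5,
                                            tail_mode="separate")
        # identical clusters; separate-tail p can only be smaller or equal
        assert joint.n_clusters == sep.n_clusters
        assert (sep.p_value <= joint.p_value + 1e-12).all()


class TestTwoGroups:
    def test_null_groups_rarely_significant(self, rng):
        n_false = 0
        for i in range(40):
            a = 0.5 + rng.normal(0, 0.03, (8, 40))
            b = 0.5 + rng.normal(0, 0.03, (8, 40))
            res = cluster_permutation_two_groups(a, b, n_perm=200, seed=i)
            n_false += bool(res.significant())
        assert n_false <= 5  # ~5% nominal; allow Monte-Carlo slack

    def test_block_difference_localized(self, rng):
        a = block_maps(rng, n_subjects=12)
        b = 0.5 + rng.normal(0, 0.02, (12, 50))
        res = cluster_permutation_two_groups(a, b, n_perm=500, seed=1)
        sig = res.significant()
        assert len(sig) == 1
        members = np.sort(res.clusters[sig[0]][:, 0])
        assert members.min() >= 19 and members.max() <= 30

    def test_swapping_groups_flips_sign(self, rng):
        a = block_maps(rng, n_subjects=10)
        b = 0.5 + rng.normal(0, 0.02, (10, 50))
        r1 = cluster_permutation_two_groups(a, b, n_perm=300, seed=2)
        r2 = cluster_permutation_two_groups(b, a, n_perm=300, seed=2)
        np.testing.assert_allclose(np.sort(r1.mass), -np.sort(r2.mass)[::-1])


def synthetic_tg(rng, kind, n_subjects=15, T=40, sd=0.02):
    """Subject TG stacks with known structure: 'flat' square vs 'diagonal'."""
    A = 0.5 + rng.normal(0, sd, (n_subjects, T, T))
    if kind == "flat":
        A[:, 10:30, 10:30] += 0.2
    elif kind == "diagonal":
        for t in range(10, 30):
            A[:, max(10, t - 1):min(30, t + 2), t] += 0.2
    return A


class TestSpecificity:
    def _diag_result(self, A, seed=0):
        T = A.shape[1]
        diag = A[:, np.arange(T), np.arange(T)]
        return cluster_permutation_vs_chance(diag, 0.5, n_perm=500, seed=seed)

    def test_stable_square_pattern_has_no_specificity(self, rng):
        A = synthetic_tg(rng, "flat")
        spec = specificity_index(A, self._diag_result(A), n_perm=300, seed=1)
        assert spec.window_mask.sum() >= 15
        assert spec.mean() < 0.05

    def test_diagonal_pattern_is_time_specific(self, rng):
        A = synthetic_tg(rng, "diagonal")
        spec = specificity_index(A, self._diag_result(A), n_perm=300, seed=1)
        assert spec.mean() > 0.8

    def test_pointwise_method_agrees_qualitatively(self, rng):
        A = synthetic_tg(rng, "diagonal")
        spec = specificity_index(A, self._diag_result(A), n_perm=300, seed=1,
                                 method="pointwise")
        assert spec.mean() > 0.8

    def test_empty_window_warns_and_returns_empty(self, rng):
        A = 0.5 + rng.normal(0, 0.02, (10, 20, 20))
        with pytest.warns(UserWarning, match="no significant"):
            spec = specificity_index(A, self._diag_result(A), n_perm=200, seed=2)
        assert not spec.window_mask.any()
        assert np.isnan(spec.proportion).all()

    def test_proportions_bounded(self, rng):
        A = synthetic_tg(rng, "diagonal")
        spec = specificity_index(A, self._diag_result(A), n_perm=200, seed=3)
        vals = spec.proportion[spec.window_mask]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestMedianSplit:
    def test_even_split_24_subjects(self, rng):
        maps = 0.5 + rng.normal(0, 0.02, (24, 30))
        viv = list(rng.normal(50, 25, 24))
        high, low, _ = median_split_compare(maps, viv, n_perm=100, seed=0)
        assert len(high) == 12 and len(low) == 12
        assert set(high).isdisjoint(low)
        assert min(np.mean(viv[i]) for i in high) >= max(np.mean(viv[i]) for i in low)

    def test_odd_split_drops_middle_subject(self, rng):
        maps = 0.5 + rng.normal(0, 0.02, (25, 30))
        viv = list(rng.normal(50, 25, 25))
        high, low, _ = median_split_compare(maps, viv, n_perm=100, seed=0)
        assert len(high) == 12 and len(low) == 12
        assert len(set(high) | set(low)) == 24

    def test_ties_straddling_median_warn(self, rng):
        maps = 0.5 + rng.normal(0, 0.02, (6, 10))
        with pytest.warns(UserWarning, match="tie"):
            median_split_compare(maps, [1.0, 1.0, 1.0, 1.0, 2.0, 0.0],
                                 n_perm=100, seed=0)

    def test_null_split_rarely_significant(self, rng):
        n_false = 0
        for i in range(20):
            maps = 0.5 + rng.normal(0, 0.03, (12, 30))
            viv = list(rng.normal(50, 25, 12))
            _, _, res = median_split_compare(maps, viv, n_perm=200, seed=i)
            n_false += bool(res.significant())
        assert n_false <= 3


class TestCorrelation:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=10)
        r, p = correlation_test(x, 2 * x + 1, n_perm=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05
        r, _ = correlation_test(x, -x, n_perm=200, seed=0)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlation_test(np.ones(5), np.arange(5.0))

    def test_false_positive_rate_near_alpha(self, rng):
        # critical |r| at n=25, alpha=0.05 is 0.396; the permutation p should
        # reject ~5% of independent draws
        n_rej = 0
        n_rep = 300
        for i in range(n_rep):
            r, p = correlation_test(rng.normal(size=25), rng.normal(size=25),
                                    n_perm=200, seed=i)
            n_rej += p < 0.05
        assert 0.02 <= n_rej / n_rep <= 0.09

    def test_map_correlation_recovers_coupled_block(self, rng):
        x = rng.normal(size=20)
        maps = rng.normal(0, 1.0, (20, 40))
        maps[:, 15:25] += 2.0 * x[:, None]
        res = correlation_cluster_test(x, maps, n_perm=300, seed=1)
        sig = res.significant()
        assert len(sig) >= 1
        members = np.concatenate([res.clusters[i][:, 0] for i in sig])
        assert members.min() >= 14 and members.max() <= 25
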