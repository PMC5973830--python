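"""LCMV beamformer: rank reduction, filters, bias correction, atlas averaging."""

import numpy as np
import pytest

from tgdecode import (
    EpochsArray,
    LCMVBeamformer,
    LeadField,
    TimeWindow,
    atlas_average,
    correct_bias,
    lcmv_filters,
    make_leadfield,
    noise_bias_estimate,
    project_difference_erf,
    rank_reduce,
    sensor_covariance,
    shrink_covariance,
)


def reduced_leadfield(n_sources=10, n_sensors=30, seed=0):
    return rank_reduce(make_leadfield(n_sources, n_sensors, seed))


def noise_epochs(rng, n_trials=40, n_sensors=30, n_samples=90, fs=300.0, signal=None):
    data = rng.standard_normal((n_trials, n_sensors, n_samples))
    labels = np.arange(n_trials) % 2
    if signal is not None:
        data += np.where(labels == 1, 1.0, -1.0)[:, None, None] * signal[None]
    times = np.arange(n_samples) / fs - 0.1
    return EpochsArray(data=data, labels=labels, times=times, fs=fs)


class TestRankReduce:
    def test_normal_aligned_gain_vanishes(self):
        normal = np.array([[0.0, 0.0, 1.0]])
        gains = np.zeros((1, 3, 5))
        gains[0, 2] = np.arange(5.0)  # sensitivity purely along the normal
        lf = LeadField(gains=gains, surface_normals=normal)
        red = rank_reduce(lf)
        assert np.abs(red.gains).max() < 1e-12

    def test_tangential_gain_norm_preserved(self):
        normal = np.array([[0.0, 0.0, 1.0]])
        gains = np.zeros((1, 3, 4))
        gains[0, 0] = [1.0, 2.0, 3.0, 4.0]
        gains[0, 1] = [4.0, 3.0, 2.0, 1.0]
        lf = LeadField(gains=gains, surface_normals=normal)
        red = rank_reduce(lf)
        assert np.linalg.norm(red.gains) == pytest.approx(np.linalg.norm(gains),
                                                          abs=1e-9)

    def test_reduced_blocks_have_rank_at_most_two(self):
        red = reduced_leadfield(seed=5)
        assert red.n_orientations == 2
        for s in range(red.n_sources):
            assert np.linalg.matrix_rank(red.gains[s]) <= 2

    def test_region_labels_propagate(self):
        lf = make_leadfield(10, 20, seed=1)
        red = rank_reduce(lf)
        np.testing.assert_array_equal(red.region_labels, lf.region_labels)


class TestShrinkCovariance:
    def test_zero_gamma_is_identity(self, rng):
        A = rng.standard_normal((6, 6))
        C = A @ A.T
        np.testing.assert_array_equal(shrink_covariance(C, 0.0), C)

    def test_full_gamma_preserves_trace(self, rng):
        A = rng.standard_normal((6, 6))
        C = A @ A.T
        out = shrink_covariance(C, 1.0)
        assert np.trace(out) == pytest.approx(np.trace(C))
        assert np.allclose(out, np.diag(np.diag(out)))

    def test_small_gamma_regularizes_rank_deficient(self, rng):
        v = rng.standard_normal((6, 2))
        C = v @ v.T  # rank 2
        out = shrink_covariance(C, 0.01)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_rejects_asymmetric(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            shrink_covariance(rng.standard_normal((4, 4)), 0.1)


class TestLCMVFilters:
    def test_unit_gain_constraint(self, rng):
        red = reduced_leadfield()
        C = shrink_covariance(np.cov(rng.standard_normal((30, 500))), 0.01)
        filters = lcmv_filters(red, C)
        for s in range(red.n_sources):
            np.testing.assert_allclose(filters.filters[s] @ red.gains[s].T,
                                       np.eye(2), atol=1e-6)

    def test_invariant_to_covariance_scale(self, rng):
        red = reduced_leadfield()
        C = shrink_covariance(np.cov(rng.standard_normal((30, 500))), 0.01)
        f1 = lcmv_filters(red, C)
        f2 = lcmv_filters(red, 7.3 * C)
        np.testing.assert_allclose(f1.filters, f2.filters, rtol=1e-8)

    def test_round_trip_recovers_dipole_timecourse(self, rng):
        red = reduced_leadfield(n_sources=6, n_sensors=40, seed=2)
        s = 3
        t = np.linspace(0, 1, 300)
        moment = np.vstack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 3 * t)])
        sensor = red.gains[s].T @ moment  # sensors x time
        C = sensor @ sensor.T / t.size + 1e-6 * np.eye(40)
        filters = lcmv_filters(red, C)
        recovered = filters.filters[s] @ sensor
        for o in range(2):
            r = np.corrcoef(recovered[o], moment[o])[0, 1]
            assert r > 0.99

    def test_requires_rank_reduced_leadfield(self):
        lf = make_leadfield(3, 10, seed=0)
        with pytest.raises(ValueError, match="rank-reduced"):
            lcmv_filters(lf, np.eye(10))


class TestPowerAndBias:
    def test_quadratic_amplitude_scaling(self, rng):
        # strong signal so the difference-ERF noise floor is negligible
        red = reduced_leadfield(n_sources=5, n_sensors=30, seed=3)
        pattern = red.gains[2][0]
        n_samples = 90
        sig = np.tile(pattern[:, None], (1, n_samples))
        ep1 = noise_epochs(np.random.default_rng(0), n_trials=100, signal=1.0 * sig)
        ep2 = noise_epochs(np.random.default_rng(0), n_trials=100, signal=2.0 * sig)
        win = TimeWindow(-0.1, 0.2)
        C = shrink_covariance(sensor_covariance(ep2, win), 0.01)
        filters = lcmv_filters(red, C)
        _, p1 = project_difference_erf(filters, ep1, win)
        _, p2 = project_difference_erf(filters, ep2, win)
        assert p2[2] / p1[2] == pytest.approx(4.0, rel=0.10)

    def test_noise_floor_matches_difference_erf_power(self, rng):
        red = reduced_leadfield(n_sources=5, n_sensors=30, seed=4)
        ratios = []
        for seed in range(5):
            ep = noise_epochs(np.random.default_rng(seed), n_trials=60)
            win = TimeWindow(-0.1, 0.2)
            C = shrink_covariance(sensor_covariance(ep, win), 0.01)
            filters = lcmv_filters(red, C)
            _, raw = project_difference_erf(filters, ep, win)
            noise = noise_bias_estimate(filters, ep, win, n_perm=300, seed=seed)
            ratios.append((raw / noise).mean())
        assert 0.8 < np.mean(ratios) < 1.25

    def test_bias_estimate_deterministic(self, rng):
        red = reduced_leadfield(n_sources=4, n_sensors=30, seed=5)
        ep = noise_epochs(rng)
        win = TimeWindow(0.0, 0.15)
        C = shrink_covariance(sensor_covariance(ep, win), 0.01)
        filters = lcmv_filters(red, C)
        a = noise_bias_estimate(filters, ep, win, n_perm=100, seed=9)
        b = noise_bias_estimate(filters, ep, win, n_perm=100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_corrected_definition_and_bounds(self):
        out = correct_bias(np.array([2.0, 0.5]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(out, [1.0, -0.5])
        with pytest.raises(ValueError):
            correct_bias(np.array([1.0]), np.array([0.0]))

    def test_beamformer_model_end_to_end(self, rng):
        red = reduced_leadfield(n_sources=8, n_sensors=30, seed=6)
        pattern = red.gains[5][1]
        n_samples = 90
        env = np.zeros(n_samples)
        env[40:80] = 1.0
        ep = noise_epochs(rng, signal=0.8 * pattern[:, None] * env[None, :])
        bf = LCMVBeamformer(red, cov_window=TimeWindow(-0.1, 0.2))
        est = bf.fit(ep, power_window=TimeWindow(0.03, 0.17), n_perm=100, seed=0)
        assert int(np.argmax(est.corrected)) == 5
        assert est.noise_power.min() > 0
        assert est.corrected.min() >= -1.0


class TestAtlasAverage:
    def test_constant_sources_give_constant_regions(self):
        labels = np.array([1, 1, 2, 2, 3])
        out = atlas_average(np.full(5, 3.3), labels)
        assert out == {1: pytest.approx(3.3), 2: pytest.approx(3.3),
                       3: pytest.approx(3.3)}

    def test_74_regions_give_74_values(self, rng):
        labels = np.repeat(np.arange(1, 75), 3)
        out = atlas_average(rng.standard_normal(labels.size), labels)
        assert len(out) == 74

    def test_invariant_to_source_permutation(self, rng):
        labels = rng.integers(1, 5, 30)
        vals = rng.standard_normal(30)
        perm = rng.permutation(30)
        a = atlas_average(vals, labels)
        b = atlas_average(vals[perm], labels[perm])
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_group_level_averages_subjects_first(self, rng):
        labels = np.array([1, 1, 2])
        vals = np.array([[1.0, 3.0, 5.0], [3.0, 5.0, 7.0]])
        out = atlas_average(vals, labels)
        assert out == {1: pytest.approx(3.0), 2: pytest.approx(6.0)}
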