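import math
from dataclasses import replace

import numpy as np
import pytest

from crossgen.covariance import pooled_noise_covariance
from crossgen.datasets import TrialSet
from crossgen.exceptions import ValidationError
from crossgen.metrics import cross_generalization, cv_information
from crossgen.mixing import (
    MixingSimConfig,
    _simulate_stats,
    calibrate_signal_scale,
    draw_patterns,
    false_positive_rate,
    gaussian_mixing_matrix,
    run_mixing_experiment,
    simulate_context_trials,
)


class TestMixingMatrix:
    def test_matches_elementwise_kernel_oracle(self):
        mat = gaussian_mixing_matrix(100, 10, 25.0)
        for k in range(10):
            center = (k + 0.5) * 100 / 10 - 0.5
            row = np.array(
                [math.exp(-0.5 * ((j - center) / 25.0) ** 2) for j in range(100)]
            )
            row /= row.sum()
            np.testing.assert_allclose(mat[k], row, atol=1e-12)

    def test_rows_peak_at_center_and_decay(self):
        mat = gaussian_mixing_matrix(100, 10, 25.0)
        for k in range(10):
            peak = np.argmax(mat[k])
            assert abs(peak - ((k + 0.5) * 10 - 0.5)) <= 1
            assert np.all(np.diff(mat[k][: peak + 1]) >= -1e-15)
            assert np.all(np.diff(mat[k][peak:]) <= 1e-15)

    def test_huge_sd_approaches_uniform_average(self):
        mat = gaussian_mixing_matrix(100, 5, 1e6)
        np.testing.assert_allclose(mat, np.full((5, 100), 0.01), atol=1e-9)

    def test_validation(self):
        with pytest.raises(ValidationError):
            gaussian_mixing_matrix(10, 2, 0.0)


class TestDrawPatterns:
    def test_full_uniformity_makes_all_selective_weights_positive(self):
        cfg = MixingSimConfig(uniformity=1.0, n_repetitions=20)
        for pat in draw_patterns(cfg, np.random.default_rng(0)):
            for c, sel in enumerate(pat.selective_sets):
                assert np.all(pat.weights[c, sel] > 0)

    def test_full_stability_shares_identical_weights(self):
        cfg = MixingSimConfig(stability=1.0, n_repetitions=20)
        pats = draw_patterns(cfg, np.random.default_rng(1))
        for pat in pats[1:]:
            np.testing.assert_array_equal(pat.weights, pats[0].weights)

    def test_patterns_are_exactly_orthogonal(self):
        cfg = MixingSimConfig(uniformity=0.7, stability=0.5)
        for pat in draw_patterns(cfg, np.random.default_rng(2)):
            assert float(pat.weights[0] @ pat.weights[1]) == 0.0

    @pytest.mark.parametrize("stability", [0.0, 0.25, 0.5, 1.0])
    def test_across_repetition_correlation_tracks_stability(self, stability):
        """Monte-Carlo oracle: correlation of selective weights between two
        repetitions approximates the stability parameter."""
        from crossgen.mixing import _pattern_batch

        cfg = MixingSimConfig(stability=stability, n_repetitions=2,
                              n_neurons=20)
        w, sets = _pattern_batch(np.random.default_rng(3), cfg, n_runs=4000)
        sel = np.take_along_axis(
            w, np.broadcast_to(sets[:, None], (4000, 2, 2, 10)), axis=3
        )
        x = sel[:, 0].ravel()
        y = sel[:, 1].ravel()
        corr = np.corrcoef(x, y)[0, 1]
        assert corr == pytest.approx(stability, abs=0.05)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            MixingSimConfig(uniformity=1.5)
        with pytest.raises(ValidationError):
            MixingSimConfig(stability=-0.1)


class TestSimulateContextTrials:
    def test_zero_signal_null_information(self, rng):
        vals = []
        for _ in range(200):
            data, labels = simulate_context_trials(
                np.ones(4), 0.0, 40, rng
            )
            ts = TrialSet(data=data, labels=labels)
            from crossgen.covariance import NoiseCovariance
            from crossgen.datasets import make_folds

            cov = NoiseCovariance(np.eye(4), 0.0)
            vals.append(cv_information(ts, cov, make_folds(labels, rng)).value)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / math.sqrt(len(vals))

    def test_noiseless_mean_difference_equals_pattern(self, rng):
        pattern = np.array([1.0, -2.0, 0.5])
        data, labels = simulate_context_trials(pattern, 1.0, 10, rng,
                                               noise=False)
        diff = data[labels == 1].mean(0) - data[labels == 2].mean(0)
        np.testing.assert_allclose(diff, pattern, atol=1e-14)

    def test_determinism_and_validation(self):
        pattern = np.ones(3)
        d1, _ = simulate_context_trials(pattern, 1.0, 8,
                                        np.random.default_rng(7))
        d2, _ = simulate_context_trials(pattern, 1.0, 8,
                                        np.random.default_rng(7))
        np.testing.assert_array_equal(d1, d2)
        with pytest.raises(ValidationError):
            simulate_context_trials(pattern, 1.0, 7, np.random.default_rng(0))


class TestEngineEquivalence:
    def test_batch_engine_matches_trialset_api(self):
        """The vectorised simulation engine reproduces the public
        per-TrialSet pipeline (pooled covariance + crossnobis) to 1e-10."""
        cfg = MixingSimConfig(
            n_neurons=12, n_sensors=4, mixing_sd=3.0,
            n_trials_per_context=40, n_repetitions=3,
            uniformity=0.6, stability=0.4,
        )
        gen, info, trials, labels, folds = _simulate_stats(
            np.random.default_rng(42), cfg, scale=0.8, n_runs=2,
            return_trials=True,
        )
        for run in range(2):
            for rep in range(3):
                ts = [
                    TrialSet(data=trials[run, rep, c], labels=labels,
                             context_id=str(c))
                    for c in range(2)
                ]
                cov = pooled_noise_covariance(ts, shrinkage=cfg.shrinkage)
                for c in range(2):
                    v = cv_information(ts[c], cov, folds).value
                    assert v == pytest.approx(info[run, rep, c], abs=1e-10)
                g = cross_generalization(ts[0], ts[1], cov, folds, folds)
                assert g == pytest.approx(gen[run, rep], abs=1e-10)


class TestCalibration:
    def test_zero_target_gives_zero_scale(self):
        cfg = MixingSimConfig()
        assert calibrate_signal_scale(0.0, cfg) == 0.0

    def test_self_consistency_at_quarter_distance(self):
        """Re-simulating at the calibrated scale reproduces the target
        distance within the 5% calibration tolerance plus Monte-Carlo
        allowance."""
        cfg = MixingSimConfig(seed=5, target_m=0.25)
        scale = calibrate_signal_scale(0.25, cfg, np.random.default_rng(5))
        probe = replace(cfg, n_repetitions=1000)
        _, info = _simulate_stats(np.random.default_rng(123), probe, scale, 1)
        sem = info.std(ddof=1) / math.sqrt(info.size)
        assert abs(info.mean() - 0.25) <= 0.05 * 0.25 + 3 * sem


class TestMixingExperiment:
    def test_deterministic_under_fixed_seed(self):
        cfg = MixingSimConfig(n_repetitions=5, n_trials_per_context=100,
                              n_neurons=20, n_sensors=4, seed=9)
        r1 = run_mixing_experiment(cfg)
        r2 = run_mixing_experiment(cfg)
        np.testing.assert_array_equal(r1.generalization, r2.generalization)
        assert r1.p == r2.p

    def test_single_sensor_uniform_patterns_generalize_everywhere(self):
        """With one global sensor and uniformity 1, nearly every repetition
        shows positive spurious generalization."""
        cfg = MixingSimConfig(
            n_sensors=1, uniformity=1.0, target_m=4.0,
            n_repetitions=20, seed=11,
        )
        scale = calibrate_signal_scale(4.0, cfg, np.random.default_rng(11))
        gen, _ = _simulate_stats(np.random.default_rng(12), cfg, scale, 3)
        assert (gen > 0).mean() >= 0.95

    def test_orthogonal_independent_patterns_average_to_zero(self):
        cfg = MixingSimConfig(uniformity=0.0, stability=0.0,
                              n_repetitions=10, seed=13)
        scale = calibrate_signal_scale(0.25, cfg, np.random.default_rng(13))
        gen, _ = _simulate_stats(np.random.default_rng(14), cfg, scale, 30)
        sem = gen.std(ddof=1) / math.sqrt(gen.size)
        assert abs(gen.mean()) < 3 * sem


class TestFalsePositiveRate:
    def test_identity_mixing_restores_nominal_rate(self):
        """Without mixing (identity sensor matrix) spuriousness disappears
        even at full uniformity and stability."""
        import scipy.stats

        cfg = MixingSimConfig(
            n_neurons=30, n_sensors=30, identity_mixing=True,
            uniformity=1.0, stability=1.0, target_m=4.0,
            n_trials_per_context=200, n_repetitions=10, n_runs=150, seed=21,
        )
        res = false_positive_rate(cfg)
        lo = scipy.stats.binom.ppf(0.005, 150, 0.05) / 150
        hi = scipy.stats.binom.ppf(0.995, 150, 0.05) / 150
        assert lo <= res.proportion <= hi

    def test_ci_and_counts_are_consistent(self):
        cfg = MixingSimConfig(
            n_neurons=20, n_sensors=5, n_trials_per_context=100,
            n_repetitions=8, n_runs=40, target_m=0.25, seed=23,
        )
        res = false_positive_rate(cfg)
        assert res.proportion == res.n_significant / res.n_runs
        assert 0.0 <= res.ci_low <= res.proportion <= res.ci_high <= 1.0
        assert len(res.group_p) == 40
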