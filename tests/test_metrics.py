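import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossgen.covariance import NoiseCovariance, pooled_noise_covariance
from crossgen.datasets import TrialSet, make_folds
from crossgen.exceptions import DimensionError, FoldError, ValidationError
from conftest import make_gaussian_trialset
from crossgen.metrics import (
    cross_generalization,
    cv_information,
    estimation_bias,
    expected_generalization_identity,
    generalization_estimate,
    identity_simulation_study,
    min_information_reference,
    relative_generalization,
)

IDENTITY3 = NoiseCovariance(matrix=np.eye(3), shrinkage=0.0)


def loop_crossnobis(data_train, labels_train, data_test, labels_test, cov):
    """Explicit-loop oracle: means, inverse, bilinear product."""
    def mean_diff(data, labels):
        m1 = [0.0] * data.shape[1]
        m2 = [0.0] * data.shape[1]
        n1 = n2 = 0
        for x, lab in zip(data, labels):
            if lab == 1:
                m1 = [a + b for a, b in zip(m1, x)]
                n1 += 1
            else:
                m2 = [a + b for a, b in zip(m2, x)]
                n2 += 1
        return np.array([a / n1 - b / n2 for a, b in zip(m1, m2)])

    d_train = mean_diff(data_train, labels_train)
    d_test = mean_diff(data_test, labels_test)
    inv = np.linalg.inv(cov)
    total = 0.0
    for i in range(len(d_train)):
        for j in range(len(d_test)):
            total += d_train[i] * inv[i, j] * d_test[j]
    return total


class TestCvInformation:
    def test_forced_bilinear_value(self):
        # both folds' class mean difference is exactly (2, 0, 0)
        data = np.array(
            [[1, 0, 0], [-1, 0, 0], [1, 0, 0], [-1, 0, 0]], dtype=float
        )
        ts = TrialSet(data=data, labels=np.array([1, 2, 1, 2]))
        folds = np.array([1, 1, 2, 2])
        est = cv_information(ts, IDENTITY3, folds)
        assert est.value == pytest.approx(4.0, abs=1e-12)
        np.testing.assert_allclose(est.per_fold_values, [4.0, 4.0])

    def test_matches_explicit_loop_oracle(self, small_trialset):
        folds = np.array([1, 1, 1, 2, 2, 2])
        cov = pooled_noise_covariance(small_trialset, shrinkage=0.2)
        est = cv_information(small_trialset, cov, folds)
        d = small_trialset.data
        lab = small_trialset.labels
        v12 = loop_crossnobis(d[:3], lab[:3], d[3:], lab[3:], cov.matrix)
        v21 = loop_crossnobis(d[3:], lab[3:], d[:3], lab[:3], cov.matrix)
        assert est.value == pytest.approx(0.5 * (v12 + v21), abs=1e-10)

    def test_unbiased_under_label_permutation(self, small_trialset, rng):
        """Monte-Carlo mean under permuted labels is within 3 SE of 0."""
        n_draws = 4000
        values = np.empty(n_draws)
        data = rng.standard_normal((16, 3)) + np.array([0.5, -0.2, 0.1])
        base_labels = np.r_[np.ones(8, dtype=int), np.full(8, 2, dtype=int)]
        for i in range(n_draws):
            labels = rng.permutation(base_labels)
            ts = TrialSet(data=data, labels=labels)
            folds = make_folds(labels, rng)
            values[i] = cv_information(ts, IDENTITY3, folds).value
        se = values.std(ddof=1) / math.sqrt(n_draws)
        assert abs(values.mean()) < 3 * se

    def test_fold_all_one_class_raises(self):
        data = np.zeros((4, 3)) + np.arange(12).reshape(4, 3)
        ts = TrialSet(data=data, labels=np.array([1, 1, 2, 2]))
        with pytest.raises(FoldError):
            cv_information(ts, IDENTITY3, np.array([1, 1, 2, 2]))


class TestCrossGeneralization:
    def test_matches_explicit_loop_oracle(self, small_trialset, rng):
        data_b = rng.standard_normal((6, 3))
        ts_b = TrialSet(data=data_b, labels=np.array([2, 1, 1, 2, 2, 1]),
                        context_id="B")
        cov = pooled_noise_covariance([small_trialset, ts_b], shrinkage=0.1)
        fa = np.array([1, 2, 1, 2, 1, 2])
        fb = np.array([2, 1, 2, 1, 2, 1])
        val = cross_generalization(small_trialset, ts_b, cov, fa, fb)
        da, la = small_trialset.data, small_trialset.labels
        db, lb = ts_b.data, ts_b.labels
        v1 = loop_crossnobis(da[fa == 1], la[fa == 1], db[fb == 2], lb[fb == 2],
                             cov.matrix)
        v2 = loop_crossnobis(da[fa == 2], la[fa == 2], db[fb == 1], lb[fb == 1],
                             cov.matrix)
        assert val == pytest.approx(0.5 * (v1 + v2), abs=1e-10)
        # symmetric in its two contexts
        val_sym = cross_generalization(ts_b, small_trialset, cov, fb, fa)
        assert val == pytest.approx(val_sym, abs=1e-10)

    def test_identical_representations_recover_information(self, rng):
        """E[cross-gen] matches the true within-context value when the two
        contexts share the difference vector (2,0,0) -> M = 4."""
        vals = []
        for _ in range(300):
            a = make_gaussian_trialset(rng, [2, 0, 0], n_trials=64)
            b = make_gaussian_trialset(rng, [2, 0, 0], n_trials=64,
                                       context_id="B")
            vals.append(
                cross_generalization(a, b, IDENTITY3, rng=rng)
            )
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - 4.0) < 3 * se

    def test_orthogonal_representations_have_zero_mean(self, rng):
        vals = []
        for _ in range(300):
            a = make_gaussian_trialset(rng, [1, 0, 0], n_trials=64)
            b = make_gaussian_trialset(rng, [0, 1, 0], n_trials=64,
                                       context_id="B")
            vals.append(cross_generalization(a, b, IDENTITY3, rng=rng))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_self_consistency_with_cv_information(self, rng):
        """Two independent samples of one representation: cross-gen and
        within-sample information share their expectation (3-SE band)."""
        gen, info = [], []
        for _ in range(300):
            a = make_gaussian_trialset(rng, [1.0, 0.5, 0], n_trials=48)
            b = make_gaussian_trialset(rng, [1.0, 0.5, 0], n_trials=48,
                                       context_id="B")
            fa, fb = make_folds(a.labels, rng), make_folds(b.labels, rng)
            gen.append(cross_generalization(a, b, IDENTITY3, fa, fb))
            info.append(cv_information(a, IDENTITY3, fa).value)
        gen, info = np.asarray(gen), np.asarray(info)
        diff = gen - info
        se = diff.std(ddof=1) / math.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_channel_mismatch_raises(self, small_trialset, rng):
        other = TrialSet(data=rng.standard_normal((4, 2)),
                         labels=np.array([1, 2, 1, 2]))
        with pytest.raises(DimensionError):
            cross_generalization(small_trialset, other, IDENTITY3, rng=rng)


class TestReferenceValues:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(3.0, 3.0, 3.0), (4.0, 1.0, 2.0), (-1.0, 4.0, 0.0), (0.0, 5.0, 0.0)],
    )
    def test_expected_generalization_identity(self, a, b, expected):
        assert expected_generalization_identity(a, b) == pytest.approx(expected)

    def test_expected_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            expected_generalization_identity(np.nan, 1.0)

    @pytest.mark.parametrize("a, b, expected", [(4.0, 1.0, 1.0), (3.0, 3.0, 3.0)])
    def test_min_information_reference(self, a, b, expected):
        assert min_information_reference(a, b) == expected

    @given(
        a=st.floats(1e-6, 1e6),
        b=st.floats(1e-6, 1e6),
    )
    @settings(derandomize=True, max_examples=200)
    def test_geometric_mean_dominates_minimum(self, a, b):
        geo = expected_generalization_identity(a, b)
        mn = min_information_reference(a, b)
        assert geo >= mn * (1 - 1e-12)
        if not math.isclose(a, b):
            assert geo > mn

    @pytest.mark.parametrize(
        "emp, exp, result", [(2.0, 2.0, 1.0), (0.0, 2.0, 0.0)]
    )
    def test_relative_generalization(self, emp, exp, result):
        assert relative_generalization(emp, exp) == result

    def test_relative_generalization_undefined_marker(self):
        assert math.isnan(relative_generalization(1.0, 0.0))
        assert math.isnan(relative_generalization(1.0, -2.0))

    @pytest.mark.parametrize(
        "est, truth, bias", [(4.0, 4.0, 0.0), (2.0, 4.0, -0.5)]
    )
    def test_estimation_bias(self, est, truth, bias):
        assert estimation_bias(est, truth) == pytest.approx(bias)

    def test_estimation_bias_zero_truth(self):
        with pytest.raises(ValidationError):
            estimation_bias(1.0, 0.0)


class TestIdentityStudy:
    def test_lower_bound_and_shrinking_gap(self):
        """Geometric-mean estimate under-estimates true generalization;
        the gap shrinks with more trials."""
        gaps = []
        for n_trials, seed in ((200, 1), (1000, 2)):
            df = identity_simulation_study(4.0, 4.0, n_sims=500,
                                           n_trials=n_trials, seed=seed)
            assert df.expected.mean() <= df.empirical.mean() + 3 * (
                (df.expected - df.empirical).std() / math.sqrt(len(df))
            )
            gaps.append(df.empirical.mean() - df.expected.mean())
        assert gaps[0] > gaps[1]

    def test_min_reference_worse_with_unequal_snr(self):
        """With M = 4 vs 0.25 the minimum reference under-estimates the
        true generalization far more than the geometric-mean estimate."""
        df = identity_simulation_study(4.0, 0.25, n_sims=500, seed=3)
        truth = df.truth.iloc[0]
        bias_geo = estimation_bias(df.expected.mean(), truth)
        bias_min = estimation_bias(df.min_reference.mean(), truth)
        assert bias_min < bias_geo <= 0.1
        assert abs(bias_geo) < abs(bias_min)


def test_generalization_estimate_bundles_references(rng):
    a = make_gaussian_trialset(rng, [2, 0, 0], n_trials=64)
    b = make_gaussian_trialset(rng, [2, 0, 0], n_trials=64, context_id="B")
    est = generalization_estimate(a, b, IDENTITY3, rng=rng)
    assert est.expected_identity >= est.min_reference - 1e-12
    if est.expected_identity > 0:
        assert est.relative == pytest.approx(
            est.empirical / est.expected_identity
        )
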