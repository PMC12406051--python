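"""ITEM model inversion: weights, prediction, cross-validation, metrics."""

import numpy as np
import pytest

from itemsl.decoding import (
    ItemModel,
    balanced_accuracy,
    classify,
    crossvalidate,
    decoding_accuracy,
    fit_item_weights,
    median_absolute_error,
    predict_design,
    predictive_correlation,
)
from itemsl.design import TransformationMatrix
from itemsl.estimators import TrialEstimates


def indicator_T(labels, p):
    T = np.zeros((len(labels), p))
    T[np.arange(len(labels)), labels] = 1.0
    return T


def random_spd(t, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(t, t + 4))
    return A @ A.T / (t + 4)


class TestFitItemWeights:
    def test_identity_case(self):
        T = indicator_T([0, 1, 0, 1], 2)
        W = fit_item_weights(T, np.eye(4), T)
        np.testing.assert_allclose(W, np.eye(2), atol=1e-10)

    def test_inversion_identity(self):
        """Noiseless gamma = T @ B with invertible B: W = B^-1, gamma @ W = T."""
        rng = np.random.default_rng(0)
        T = indicator_T(rng.integers(0, 2, 20), 2)
        B = rng.normal(size=(2, 2)) + 3 * np.eye(2)
        gamma = T @ B
        W = fit_item_weights(gamma, random_spd(20, 1), T)
        np.testing.assert_allclose(W, np.linalg.inv(B), atol=1e-8)
        np.testing.assert_allclose(gamma @ W, T, atol=1e-8)

    def test_matches_brute_force_gls(self):
        rng = np.random.default_rng(2)
        gamma = rng.normal(size=(40, 6))
        T = indicator_T(rng.integers(0, 2, 40), 2)
        U = random_spd(40, 3)
        W = fit_item_weights(gamma, U, T)
        Ui = np.linalg.inv(U)
        expected = np.linalg.inv(gamma.T @ Ui @ gamma) @ gamma.T @ Ui @ T
        np.testing.assert_allclose(W, expected, atol=1e-8)

    def test_whitening_equivalence(self):
        """GLS weights equal OLS on U-whitened responses and targets."""
        rng = np.random.default_rng(4)
        gamma = rng.normal(size=(30, 5))
        T = indicator_T(rng.integers(0, 2, 30), 2)
        U = random_spd(30, 5)
        W = fit_item_weights(gamma, U, T)
        Linv = np.linalg.inv(np.linalg.cholesky(U))
        W_ols = np.linalg.lstsq(Linv @ gamma, Linv @ T, rcond=None)[0]
        np.testing.assert_allclose(W, W_ols, atol=1e-8)

    def test_singular_without_fallback(self):
        rng = np.random.default_rng(6)
        gamma = rng.normal(size=(10, 20))  # more voxels than trials
        T = indicator_T(rng.integers(0, 2, 10), 2)
        with pytest.raises(np.linalg.LinAlgError, match="pinv"):
            fit_item_weights(gamma, np.eye(10), T)
        W = fit_item_weights(gamma, np.eye(10), T, allow_pinv=True)
        assert np.all(np.isfinite(W))


class TestPredictDesign:
    def test_zero_weights(self):
        assert np.all(predict_design(np.zeros((3, 2)), np.ones((5, 3))) == 0)

    def test_single_trial(self):
        assert predict_design(np.ones((3, 2)), np.ones((1, 3))).shape == (1, 2)

    def test_voxel_mismatch(self):
        with pytest.raises(ValueError, match="voxels"):
            predict_design(np.zeros((3, 2)), np.ones((5, 4)))


class TestCrossvalidate:
    def make_estimates(self, n_sessions, t=12, v=4, seed=0):
        rng = np.random.default_rng(seed)
        gamma = rng.normal(size=(n_sessions * t, v))
        sids = np.repeat(np.arange(n_sessions), t)
        U = {s: np.eye(t) for s in range(n_sessions)}
        labels = rng.integers(0, 2, n_sessions * t)
        return TrialEstimates(gamma, sids, U), indicator_T(labels, 2)

    @pytest.mark.parametrize("n_sessions", [2, 8])
    def test_one_fold_per_session(self, n_sessions):
        est, T = self.make_estimates(n_sessions)
        res = crossvalidate(est, T, use_reml=False)
        assert len(np.unique(res.fold_ids)) == n_sessions

    def test_folds_partition_trials(self):
        est, T = self.make_estimates(3)
        res = crossvalidate(est, T, use_reml=False)
        # every trial predicted exactly once; fold == session index
        np.testing.assert_array_equal(res.fold_ids, np.repeat(np.arange(3), 12))
        assert res.predicted.shape == T.shape

    def test_single_session_errors(self):
        est, T = self.make_estimates(1)
        with pytest.raises(ValueError, match="sessions"):
            crossvalidate(est, T)

    def test_noiseless_recovery_through_cv(self):
        rng = np.random.default_rng(7)
        labels = np.tile([0, 1], 12)
        T = indicator_T(labels, 2)
        B = rng.normal(size=(2, 2)) + 3 * np.eye(2)
        gamma = T @ B
        est = TrialEstimates(gamma, np.repeat([0, 1], 12), {0: np.eye(12), 1: np.eye(12)})
        res = crossvalidate(est, T, use_reml=False)
        np.testing.assert_allclose(res.predicted, T, atol=1e-8)

    def test_chance_level_with_shuffled_labels(self):
        """Labels independent of responses: mean CV accuracy ~ 50%."""
        rng = np.random.default_rng(8)
        accs = []
        for _ in range(200):
            gamma = rng.normal(size=(40, 6))
            labels = np.tile([0, 1], 20)
            rng.shuffle(labels)
            est = TrialEstimates(
                gamma, np.repeat([0, 1], 20), {0: np.eye(20), 1: np.eye(20)}
            )
            res = crossvalidate(est, indicator_T(labels, 2), use_reml=False)
            accs.append(decoding_accuracy(classify(res.predicted), labels))
        assert abs(np.mean(accs) - 0.5) < 0.03


class TestMetrics:
    def test_classify_argmax_and_ties(self):
        assert classify(np.array([[0.8, 0.2]]))[0] == 0
        assert classify(np.array([[0.5, 0.5]]))[0] == 0  # tie -> lowest index
        np.testing.assert_array_equal(classify(np.eye(4)), np.arange(4))

    def test_decoding_accuracy_examples(self):
        truth = np.zeros(100, int)
        labels = truth.copy()
        labels[:25] = 1
        assert decoding_accuracy(labels, truth) == 0.75
        assert decoding_accuracy(truth, truth) == 1.0

    def test_accuracy_random_labels_binomial(self):
        rng = np.random.default_rng(9)
        truth = np.tile([0, 1], 5000)
        labels = rng.integers(0, 2, 10000)
        assert decoding_accuracy(labels, truth) == pytest.approx(0.5, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            decoding_accuracy(np.array([]), np.array([]))

    def test_balanced_accuracy_weights_classes_equally(self):
        truth = np.array([0] * 90 + [1] * 10)
        labels = np.zeros(100, int)  # always predict majority
        assert decoding_accuracy(labels, truth) == 0.9
        assert balanced_accuracy(labels, truth) == 0.5

    def test_correlation_examples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert predictive_correlation(x, x) == pytest.approx(1.0)
        assert predictive_correlation(-x, x) == pytest.approx(-1.0)

    def test_correlation_five_point_toy_hand_formula(self):
        pred = np.array([0.2, 1.1, 0.9, 2.2, 1.8])
        act = np.array([0.0, 1.0, 1.0, 2.0, 2.0])
        n = 5
        num = n * np.sum(pred * act) - pred.sum() * act.sum()
        den = np.sqrt(n * np.sum(pred**2) - pred.sum() ** 2) * np.sqrt(
            n * np.sum(act**2) - act.sum() ** 2
        )
        assert predictive_correlation(pred, act) == pytest.approx(num / den)

    def test_constant_actual_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = predictive_correlation(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert np.isnan(out)

    def test_correlation_needs_three_trials(self):
        with pytest.raises(ValueError):
            predictive_correlation(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_median_absolute_error(self):
        assert median_absolute_error(np.array([1.0, 2.0, 10.0]), np.array([1.0, 1.0, 1.0])) == 1.0


class TestItemModelResults:
    def make_fitted(self):
        rng = np.random.default_rng(10)
        labels = np.tile([0, 1], 20)
        T = TransformationMatrix(
            np.column_stack([
                indicator_T(labels, 2),
                rng.uniform(0, 1, 40),
            ]),
            ["A", "B", "intensity"],
            ["indicator", "indicator", "parametric"],
        )
        signal = T.matrix @ rng.normal(size=(3, 6)) + 0.3 * rng.normal(size=(40, 6))
        est = TrialEstimates(
            signal, np.repeat([0, 1], 20), {0: np.eye(20), 1: np.eye(20)}
        )
        return ItemModel(est, T, use_reml=False).fit()

    def test_summary_reports_metrics(self):
        res = self.make_fitted()
        s = res.summary()
        assert "decoding accuracy" in s
        assert "intensity" in s
        assert res.accuracy() > 0.8
        assert res.correlation("intensity") > 0.5

    def test_per_fold_and_frame(self):
        res = self.make_fitted()
        assert len(res.per_fold()) == 2
        frame = res.to_frame()
        assert frame.shape[0] == 40
        assert "predicted_intensity" in frame.columns
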