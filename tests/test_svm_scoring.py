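from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from radpipe.svm_scoring import (
    SelectionConfig,
    SVMModel,
    cross_validated_scores,
    cv_objective,
    sequential_forward_selection,
    standardize,
    svm_score,
    train_svm,
)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        x = rng.normal(5, 3, size=(50, 4))
        z, _, _, _ = standardize(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)

    def test_apply_row_at_training_mean_is_zero(self, rng):
        x = rng.normal(size=(30, 3))
        _, applied, _, _ = standardize(x, x.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(applied, 0, atol=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _, _, scale = standardize(x)
        assert scale[1] == 1.0
        np.testing.assert_allclose(z[:, 1], 0.0)


def _dual_qp_oracle(X, y, C):
    """Brute-force solution of the soft-margin dual on the kernel matrix."""
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2)
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    n = len(y)
    res = minimize(neg_dual, np.full(n, C / 2), method="SLSQP",
                   bounds=[(0, C)] * n,
                   constraints={"type": "eq", "fun": lambda a: a @ y},
                   options={"ftol": 1e-14, "maxiter": 1000})
    a = res.x
    sv = a > 1e-8
    margin = sv & (a < C - 1e-8)
    b_vals = [y[i] - (a * y * K[i]).sum() for i in np.flatnonzero(margin)]
    b = float(np.mean(b_vals))

    def score(x):
        d = ((X - x) ** 2).sum(axis=1)
        return float((a * y * np.exp(-d)).sum() + b)

    return a, b, score


class TestTrainSVM:
    def test_two_point_symmetric_problem_matches_qp_oracle(self):
        X = np.array([[0.5], [-0.5]])
        y = np.array([1, 0])
        model = train_svm(X, y, C=10.0, tol=1e-10)
        a, b, score = _dual_qp_oracle(X, np.array([1, -1]), C=10.0)
        assert model.bias == pytest.approx(b, abs=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)   # by symmetry
        for x in ([0.0], [0.3], [-1.2], [2.0]):
            assert svm_score(model, np.array(x)) == pytest.approx(
                score(np.array(x)), abs=1e-6)

    def test_random_problem_matches_qp_oracle(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=12) > 0, 1, 0)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        model = train_svm(X, y, C=2.0, tol=1e-10)
        _, _, score = _dual_qp_oracle(X, np.where(y == 1, 1, -1), C=2.0)
        for x in rng.normal(size=(5, 2)):
            assert svm_score(model, x) == pytest.approx(score(x), abs=1e-5)

    def test_separable_clusters_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        model = train_svm(*standardize(X)[:1], y, C=10.0)
        pred = (svm_score(model, standardize(X)[0]) > 0).astype(int)
        assert (pred == y).all()

    def test_kkt_conditions(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.uniform(size=40) > 0.5).astype(int)
        C = 1.5
        model = train_svm(X, y, C=C)
        assert (model.weights >= 0).all() and (model.weights <= C + 1e-8).all()
        assert abs((model.weights * model.labels).sum()) < 1e-8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), np.ones(5))


class TestSVMScore:
    def test_single_support_vector_identity(self):
        model = SVMModel(support_vectors=np.array([[1.0, 2.0]]),
                         weights=np.array([0.5]), labels=np.array([1]),
                         bias=0.1, C=1.0)
        assert svm_score(model, np.array([1.0, 2.0])) == pytest.approx(0.6)

    def test_far_point_decays_to_bias(self):
        model = SVMModel(support_vectors=np.array([[0.0]]),
                         weights=np.array([0.9]), labels=np.array([-1]),
                         bias=0.25, C=1.0)
        assert svm_score(model, np.array([100.0])) == pytest.approx(0.25, abs=1e-12)

    def test_matches_termwise_hand_expansion(self, rng):
        sv = rng.normal(size=(5, 3))
        w = rng.uniform(0.1, 0.9, 5)
        lab = rng.choice([-1, 1], 5)
        model = SVMModel(support_vectors=sv, weights=w, labels=lab, bias=0.3, C=1.0)
        x = rng.normal(size=3)
        expected = 0.3
        for n in range(5):   # the printed expansion, term by term
            expected += w[n] * lab[n] * np.exp(-((sv[n] - x) ** 2).sum())
        assert svm_score(model, x) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_weight_sum(self, rng):
        sv = rng.normal(size=(6, 2))
        w = rng.uniform(0, 1, 6)
        lab = rng.choice([-1, 1], 6)
        model = SVMModel(support_vectors=sv, weights=w, labels=lab, bias=-0.2, C=1.0)
        bound = w.sum() + abs(model.bias)
        for x in rng.normal(scale=3, size=(50, 2)):
            assert abs(svm_score(model, x)) <= bound + 1e-12

    def test_dimension_mismatch(self):
        model = SVMModel(support_vectors=np.zeros((2, 3)), weights=np.ones(2),
                         labels=np.array([1, -1]), bias=0.0, C=1.0)
        with pytest.raises(ValueError):
            svm_score(model, np.zeros(2))


class TestCVObjective:
    def test_separable_feature_near_one(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, n),
                             rng.normal(size=n)])
        obj = cv_objective(X, y, [0], k_folds=5, seed=0)
        assert obj > 0.97

    def test_permuted_labels_near_chance(self, rng):
        n = 60
        X = rng.normal(size=(n, 1))
        y = np.repeat([0, 1], n // 2)
        y = rng.permutation(y)
        obj = cv_objective(X, y, [0], k_folds=5, n_repeats=100, seed=1)
        assert abs(obj - 0.5) <= 0.1

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.uniform(size=40) > 0.5).astype(int)
        a = cv_objective(X, y, [0, 2], k_folds=4, n_repeats=3, seed=7)
        b = cv_objective(X, y, [0, 2], k_folds=4, n_repeats=3, seed=7)
        assert a == b

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            cv_objective(rng.normal(size=(20, 2)), np.repeat([0, 1], 10), [])

    def test_stratified_folds_balanced(self):
        # per-fold class proportions differ from global by at most one sample
        y = np.array([0] * 70 + [1] * 30)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros((100, 1)), y):
            n1 = y[test_idx].sum()
            assert abs(n1 - 3) <= 1


class TestSequentialForwardSelection:
    @staticmethod
    def _planted(rng, n=80, noise=20):
        y = np.repeat([0, 1], n // 2)
        informative = np.column_stack([
            y * 2.0 + rng.normal(0, 0.5, n),
            -y * 2.0 + rng.normal(0, 0.5, n)])
        X = np.column_stack([rng.normal(size=(n, noise // 2)), informative,
                             rng.normal(size=(n, noise - noise // 2))])
        return X, y, (noise // 2, noise // 2 + 1)

    def test_planted_informative_found_first(self, rng):
        X, y, info = self._planted(rng)
        cfg = SelectionConfig(k_folds=5, n_repeats=2, max_features=4, seed=0)
        selected, trace, model = sequential_forward_selection(X, y, cfg)
        assert set(selected[:2]) == set(info)
        assert model.selected_features == selected

    def test_trace_objective_nondecreasing(self, rng):
        X, y, _ = self._planted(rng)
        cfg = SelectionConfig(k_folds=5, n_repeats=1, max_features=4, seed=3)
        _, trace, _ = sequential_forward_selection(X, y, cfg)
        assert all(b >= a for a, b in zip(trace.objective, trace.objective[1:]))

    def test_single_useful_candidate_then_stop(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 5.0 + rng.normal(0, 0.2, n), rng.normal(size=n)])
        cfg = SelectionConfig(k_folds=5, n_repeats=1, max_features=4, seed=0)
        selected, trace, _ = sequential_forward_selection(X, y, cfg)
        assert selected[0] == 0
        assert len(selected) <= 2   # nothing improves after the planted feature

    def test_all_noise_terminates_near_chance(self, rng):
        n = 60
        X = rng.normal(size=(n, 10))
        y = np.repeat([0, 1], n // 2)
        cfg = SelectionConfig(k_folds=5, n_repeats=2, max_features=4, seed=1)
        selected, trace, _ = sequential_forward_selection(X, y, cfg)
        assert len(selected) <= 4
        assert abs(trace.objective[-1] - 0.5) < 0.2

    def test_needs_two_candidates(self, rng):
        with pytest.raises(ValueError):
            sequential_forward_selection(rng.normal(size=(20, 1)),
                                         np.repeat([0, 1], 10))


class TestCrossValidatedScores:
    def test_out_of_fold_scores_discriminate(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 3.0 + rng.normal(0, 0.5, n), rng.normal(size=n)])
        scores = cross_validated_scores(X, y, [0], k_folds=5, seed=0)
        assert scores[y == 1].mean() > scores[y == 0].mean()

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.repeat([0, 1], 15)
        a = cross_validated_scores(X, y, [0, 1], k_folds=3, seed=5)
        b = cross_validated_scores(X, y, [0, 1], k_folds=3, seed=5)
        np.testing.assert_array_equal(a, b)
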