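"""Weighted sparse representation classifier and its l1 solver."""

import numpy as np
import pytest
from sklearn.base import clone

from oracles import slsqp_weighted_l1
from ppiwsrc.wsrc import (
    Dictionary,
    WSRClassifier,
    WsrcConfig,
    classify,
    gaussian_similarity,
    solve_weighted_l1,
    weight_matrix,
)


def make_dictionary(X):
    return Dictionary.from_samples(X.T, np.zeros(X.shape[1]))


class TestGaussianSimilarity:
    def test_identical_vectors(self, rng):
        a = rng.normal(size=8)
        assert gaussian_similarity(a, a, sigma=1.5) == 1.0

    def test_closed_form_at_two_sigma_squared(self):
        sigma = 1.5
        a = np.zeros(2)
        b = np.array([np.sqrt(2) * sigma, 0.0])
        assert gaussian_similarity(a, b, sigma) == pytest.approx(np.exp(-1))

    def test_matches_arithmetic_oracle(self, rng):
        a, b, sigma = rng.normal(size=6), rng.normal(size=6), 0.7
        expected = np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
        assert gaussian_similarity(a, b, sigma) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_similarity(np.zeros(2), np.zeros(3), 1.0)


class TestWeightMatrix:
    def setup_method(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        X /= np.linalg.norm(X, axis=0)
        self.D = Dictionary(columns=X, labels=np.zeros(10),
                            column_norms=np.ones(10))
        self.y = X[:, 4]

    def test_literal_mode_peaks_at_matching_column(self):
        w = weight_matrix(self.y, self.D, WsrcConfig())
        assert w[4] == pytest.approx(1.0)
        assert w.argmax() == 4

    def test_inverse_mode_minimum_at_matching_column(self):
        w = weight_matrix(self.y, self.D, WsrcConfig(weight_mode="inverse"))
        assert w[4] == pytest.approx(1.0)
        assert w.argmin() == 4

    def test_elementwise_oracle(self, rng):
        cfg = WsrcConfig(sigma=0.9)
        w = weight_matrix(self.y, self.D, cfg)
        expected = [
            gaussian_similarity(self.y, self.D.columns[:, i], 0.9)
            for i in range(10)
        ]
        np.testing.assert_allclose(w, expected, atol=1e-12)


class TestSolveWeightedL1:
    def test_single_column_dictionary(self):
        y = np.array([0.6, 0.8])
        D = make_dictionary(y[:, None])
        alpha = solve_weighted_l1(y, D, np.array([2.0]), epsilon=1e-6)
        assert alpha == pytest.approx([1.0], abs=1e-4)

    def test_orthogonal_columns_pick_the_match(self):
        X = np.eye(4)
        D = make_dictionary(X)
        y = X[:, 2]
        alpha = solve_weighted_l1(y, D, np.ones(4), epsilon=0.005)
        # matching column carries (almost) all the mass
        assert alpha[2] == pytest.approx(1.0, abs=0.01)
        others = np.delete(alpha, 2)
        np.testing.assert_allclose(others, 0.0, atol=1e-8)

    def test_infeasible_query_raises(self):
        X = np.array([[1.0], [0.0], [0.0]])
        D = make_dictionary(X)
        y = np.array([0.0, 1.0, 0.0])  # orthogonal to the column space
        with pytest.raises(ValueError, match="infeasible"):
            solve_weighted_l1(y, D, np.ones(1), epsilon=0.005)

    def test_small_query_norm_gives_zero_solution(self):
        X = np.eye(3)
        D = make_dictionary(X)
        alpha = solve_weighted_l1(np.full(3, 1e-4), D, np.ones(3), epsilon=0.005)
        np.testing.assert_array_equal(alpha, 0.0)

    def test_objective_matches_convex_oracle(self, rng):
        for _ in range(15):
            d, n, eps = 10, 20, 0.005
            X = rng.normal(size=(d, n))
            X /= np.linalg.norm(X, axis=0)
            D = Dictionary(columns=X, labels=np.zeros(n), column_norms=np.ones(n))
            y = X @ rng.normal(size=n) * 0.3 + rng.normal(size=d) * 0.05
            y /= np.linalg.norm(y)
            w = np.exp(rng.normal(size=n))
            alpha = solve_weighted_l1(y, D, w, eps)
            assert np.linalg.norm(y - X @ alpha) <= eps + 1e-5
            ref = slsqp_weighted_l1(y, X, w, eps)
            obj, obj_ref = w @ np.abs(alpha), w @ np.abs(ref)
            assert obj <= obj_ref * (1 + 1e-4)

    def test_feasibility_on_random_instances(self, rng):
        for _ in range(20):
            d = int(rng.integers(5, 15))
            n = int(rng.integers(d, 30))
            X = rng.normal(size=(d, n))
            X /= np.linalg.norm(X, axis=0)
            D = Dictionary(columns=X, labels=np.zeros(n), column_norms=np.ones(n))
            y = rng.normal(size=d)
            y /= np.linalg.norm(y)
            alpha = solve_weighted_l1(y, D, np.ones(n), 0.005)
            assert np.linalg.norm(y - X @ alpha) <= 0.005 + 1e-5


class TestClassify:
    def test_training_column_recovers_its_class(self):
        X = np.eye(6)  # rows are samples; the two classes are orthogonal
        y_labels = np.array([1, 1, 1, 0, 0, 0])
        D = Dictionary.from_samples(X, y_labels)
        sol = classify(X[0], D)
        assert sol.label == 1
        assert sol.residuals[1] == pytest.approx(0.0, abs=0.01)
        assert sol.score > 0

    def test_two_cluster_toy_assignment(self, rng):
        a = np.array([1.0, 0.0]) + rng.normal(size=(6, 2)) * 0.02
        b = np.array([0.0, 1.0]) + rng.normal(size=(6, 2)) * 0.02
        D = Dictionary.from_samples(np.vstack([a, b]),
                                    np.array([1] * 6 + [0] * 6))
        sol = classify(np.array([1.0, 0.0]), D)
        assert sol.label == 1
        assert sol.residuals[1] < sol.residuals[0]

    def test_exact_tie_goes_to_noninteracting(self):
        # y sits exactly between the two orthogonal class axes, so the
        # unique optimum splits coefficients evenly and residuals tie
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = Dictionary.from_samples(X, np.array([0, 1]))
        sol = classify(np.array([1.0, 1.0]), D)
        assert sol.label == 0
        assert sol.residuals[0] == pytest.approx(sol.residuals[1], abs=1e-6)

    def test_score_sign_consistent_with_label(self, rng):
        X = rng.normal(size=(30, 8))
        labels = np.array([0, 1] * 15)
        D = Dictionary.from_samples(X, labels)
        for _ in range(10):
            sol = classify(rng.normal(size=8), D)
            if sol.score > 0:
                assert sol.label == 1
            elif sol.score < 0:
                assert sol.label == 0
            else:
                assert sol.label == 0  # tie rule

    def test_huge_sigma_coincides_with_unweighted_src(self, rng):
        X = rng.normal(size=(6, 20))
        X /= np.linalg.norm(X, axis=0)
        D = Dictionary(columns=X, labels=np.array([0, 1] * 10),
                       column_norms=np.ones(20))
        y = rng.normal(size=6)
        y /= np.linalg.norm(y)
        cfg = WsrcConfig(sigma=1e6)
        w_flat = weight_matrix(y, D, cfg)
        np.testing.assert_allclose(w_flat, 1.0, atol=1e-9)
        a_weighted = solve_weighted_l1(y, D, w_flat, 0.005)
        a_plain = solve_weighted_l1(y, D, np.ones(20), 0.005)
        np.testing.assert_allclose(a_weighted, a_plain, atol=1e-8)


class TestWSRClassifierEstimator:
    @staticmethod
    def _gaussian_task(rng, noise=0.1):
        d = 60
        mu0 = rng.normal(size=d)
        mu0 /= np.linalg.norm(mu0)
        mu1 = rng.normal(size=d)
        mu1 /= np.linalg.norm(mu1)

        def draw(n):
            half = n // 2
            X = np.vstack([
                mu0 + noise * rng.normal(size=(half, d)),
                mu1 + noise * rng.normal(size=(half, d)),
            ])
            return X, np.array([0] * half + [1] * half)

        return draw(100), draw(50)

    @pytest.mark.parametrize("mode", ["literal", "inverse"])
    def test_separable_gaussians_high_accuracy(self, mode):
        rng = np.random.default_rng(42)
        (Xtr, ytr), (Xte, yte) = self._gaussian_task(rng)
        clf = WSRClassifier(weight_mode=mode).fit(Xtr, ytr)
        assert (clf.predict(Xte) == yte).mean() >= 0.95

    def test_decision_function_orders_classes(self):
        rng = np.random.default_rng(1)
        (Xtr, ytr), (Xte, yte) = self._gaussian_task(rng)
        clf = WSRClassifier().fit(Xtr, ytr)
        scores = clf.decision_function(Xte)
        preds = clf.predict(Xte)
        assert ((scores > 0) == (preds == 1)).all()

    def test_sklearn_protocol(self, rng):
        clf = WSRClassifier(sigma=2.0)
        assert clone(clf).get_params()["sigma"] == 2.0
        X = rng.normal(size=(10, 4))
        y = np.array([0, 1] * 5)
        fitted = clf.fit(X, y)
        assert fitted is clf
        assert hasattr(clf, "dictionary_")
        assert list(clf.classes_) == [0, 1]

    def test_rejects_single_class(self, rng):
        with pytest.raises(ValueError):
            WSRClassifier().fit(rng.normal(size=(4, 3)), np.zeros(4))

    def test_model_artifact_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(12, 5))
        y = np.array([0, 1] * 6)
        clf = WSRClassifier(sigma=0.8).fit(X, y)
        clf.save(tmp_path / "model.json")
        loaded = WSRClassifier.load(tmp_path / "model.json")
        q = rng.normal(size=(3, 5))
        np.testing.assert_allclose(
            loaded.decision_function(q), clf.decision_function(q), atol=1e-12
        )
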