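import numpy as np
import pytest

from phm.manifold import (
    GraphSpec,
    build_laplacian,
    decision_scores,
    evaluate,
    fit_laprls,
    fit_nystrom_laprls,
    fit_rls,
    predict,
    rbf_kernel,
)
from phm.synthetic import two_filaments


def _benchmark(n=300, seed=0):
    """Frozen two-filament semi-supervised benchmark: one labeled point at
    each filament's far end."""
    X, y = two_filaments(n, seed=seed)
    i0 = int(np.argmin(np.linalg.norm(X - np.array([-1.0, 0.0]), axis=1)))
    i1 = int(np.argmin(np.linalg.norm(X - np.array([2.0, 0.5]), axis=1)))
    mask = np.ones(n, bool)
    mask[[i0, i1]] = False
    return X, y, X[[i0, i1]], y[[i0, i1]], X[mask]


class TestLaplacian:
    def test_psd_and_constant_nullvector(self, rng):
        X = rng.normal(size=(40, 3))
        L = build_laplacian(X, GraphSpec(5, 1.0))
        assert np.abs(L - L.T).max() < 1e-12
        for _ in range(100):
            v = rng.normal(size=40)
            assert v @ L @ v >= -1e-9
        assert np.abs(L @ np.ones(40)).max() < 1e-9

    def test_two_clusters_two_zero_eigenvalues(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(100, 0.1, (20, 2))])
        L = build_laplacian(X, GraphSpec(3, 1.0))
        ev = np.sort(np.linalg.eigvalsh(L))
        assert np.sum(np.abs(ev) < 1e-8) == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_laplacian(np.zeros((3, 2)), GraphSpec(7))


class TestRls:
    def test_matches_dense_ridge_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 4))
            y = rng.integers(0, 3, 30)
            m = fit_rls(X, y, 1e-3, sigma_k=1.0)
            K = rbf_kernel(X, X, 1.0)
            Y = np.where(y[:, None] == np.unique(y)[None, :], 1.0, -1.0)
            alpha = np.linalg.solve(K + 1e-3 * 30 * np.eye(30), Y)
            assert np.abs(m.alpha - alpha).max() < 1e-8

    def test_huge_regularization_shrinks_to_majority(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([0] * 20 + [1] * 10)
        m = fit_rls(X, y, 1e9, sigma_k=1.0)
        assert np.abs(m.alpha).max() < 1e-6
        pred, scores = predict(m, rng.normal(size=(20, 2)))
        assert np.all(pred == 0)  # majority class wins the argmax of ~0± scores

    def test_interpolates_isolated_labeled_points(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        y = np.array([0, 1])
        m = fit_rls(X, y, 1e-6, sigma_k=0.5)
        pred, _ = predict(m, X)
        assert np.array_equal(pred, y)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            fit_rls(np.zeros((4, 2)), np.array([0, 0, 1, 1]), 0.0)


class TestLapRls:
    def test_gamma_i_zero_equals_rls(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        Xl, yl, Xu = X[:20], y[:20], X[20:]
        m_rls = fit_rls(Xl, yl, 1e-3, sigma_k=1.0)
        m_lap = fit_laprls(Xl, yl, Xu, 1e-3, 0.0, sigma_k=1.0)
        s1 = decision_scores(m_rls, X)
        s2 = decision_scores(m_lap, X)
        assert np.abs(s1 - s2).max() < 1e-6

    def test_objective_at_solution_not_worse_than_rls_embedding(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        l = 12
        Xl, yl, Xu = X[:l], y[:l], X[l:]
        ga, gi, sig = 1e-3, 1e-2, 1.0
        m_lap = fit_laprls(Xl, yl, Xu, ga, gi, sigma_k=sig)
        K = rbf_kernel(X, X, sig)
        L = build_laplacian(X, GraphSpec())
        Y = np.where(yl[:, None] == np.unique(yl)[None, :], 1.0, -1.0)

        def objective(alpha):
            f = K @ alpha
            loss = np.sum((Y - f[:l]) ** 2)
            return (
                loss
                + ga * l * np.trace(alpha.T @ K @ alpha)
                + gi * l / len(X) ** 2 * np.trace(f.T @ L @ f)
            )

        # embed the RLS solution (labeled-only expansion) in the pooled span
        m_rls = fit_rls(Xl, yl, ga, sigma_k=sig)
        alpha_rls = np.zeros_like(m_lap.alpha)
        alpha_rls[:l] = m_rls.alpha
        assert objective(m_lap.alpha) <= objective(alpha_rls) + 1e-9

    def test_semi_supervised_benchmark(self):
        """Two labeled points: LapRLS rides the filaments; RLS cannot."""
        X, y, Xl, yl, Xu = _benchmark()
        m_lap = fit_laprls(Xl, yl, Xu, 1e-6, 1.0, sigma_k=0.2)
        m_rls = fit_rls(Xl, yl, 1e-6, sigma_k=0.2)
        acc_lap = np.mean(predict(m_lap, X)[0] == y)
        acc_rls = np.mean(predict(m_rls, X)[0] == y)
        assert acc_lap >= 0.95
        assert acc_rls <= 0.70

    def test_negative_gamma_i_rejected(self):
        with pytest.raises(ValueError):
            fit_laprls(np.zeros((4, 2)), np.array([0, 0, 1, 1]), np.zeros((2, 2)), 1e-3, -1.0)


class TestNystrom:
    def test_full_subsample_matches_laprls(self):
        X, y, Xl, yl, Xu = _benchmark(200)
        m_lap = fit_laprls(Xl, yl, Xu, 1e-6, 1.0, sigma_k=0.2)
        m_ny = fit_nystrom_laprls(
            Xl, yl, Xu, m=200, gamma_a=1e-6, gamma_i=1.0, sigma_k=0.2, pcg_tol=1e-12
        )
        assert np.abs(decision_scores(m_lap, X) - decision_scores(m_ny, X)).max() < 1e-6

    def test_residual_contract(self):
        X, y, Xl, yl, Xu = _benchmark(200)
        m_ny = fit_nystrom_laprls(
            Xl, yl, Xu, m=100, gamma_a=1e-6, gamma_i=1.0, sigma_k=0.2, pcg_tol=1e-8
        )
        assert all(d["residual"] <= 1e-8 for d in m_ny.info["pcg"])

    def test_quarter_subsample_accuracy_close(self):
        X, y, Xl, yl, Xu = _benchmark()
        m_lap = fit_laprls(Xl, yl, Xu, 1e-6, 1.0, sigma_k=0.2)
        m_ny = fit_nystrom_laprls(
            Xl, yl, Xu, m=len(X) // 4, gamma_a=1e-6, gamma_i=1.0, sigma_k=0.2, seed=0
        )
        acc_lap = np.mean(predict(m_lap, X)[0] == y)
        acc_ny = np.mean(predict(m_ny, X)[0] == y)
        assert acc_ny >= acc_lap - 0.03

    def test_invalid_landmark_count(self):
        X, y, Xl, yl, Xu = _benchmark(100)
        with pytest.raises(ValueError):
            fit_nystrom_laprls(Xl, yl, Xu, m=0)


class TestPredict:
    def test_training_points_reproduced_with_small_gamma(self, rng):
        X = rng.normal(size=(20, 2)) * 5
        y = rng.integers(0, 2, 20)
        m = fit_rls(X, y, 1e-9, sigma_k=0.5)
        pred, _ = predict(m, X)
        assert np.array_equal(pred, y)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        m = fit_rls(X, y, 1e-3)
        Xn = rng.normal(size=(10, 2))
        perm = rng.permutation(10)
        p1, s1 = predict(m, Xn)
        p2, s2 = predict(m, Xn[perm])
        assert np.array_equal(p1[perm], p2)
        assert np.allclose(s1[perm], s2)

    def test_score_continuity(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        m = fit_rls(X, y, 1e-3, sigma_k=1.0)
        x0 = np.array([[0.3, -0.2]])
        for eps in (1e-3, 1e-5, 1e-7):
            gap = np.abs(
                decision_scores(m, x0 + eps) - decision_scores(m, x0)
            ).max()
            assert gap < 10 * eps

    def test_dimension_mismatch_rejected(self, rng):
        m = fit_rls(rng.normal(size=(10, 3)), np.arange(10) % 2, 1e-3)
        with pytest.raises(ValueError, match="dimension"):
            predict(m, np.zeros((2, 5)))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "c"])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert np.all(rep.f1 == 1.0)
        off = rep.confusion[~np.eye(3, dtype=bool)]
        assert np.all(off == 0)

    def test_f1_arithmetic(self):
        """F1 of precision 0.80 and recall 0.89 rounds to 0.84."""
        p, r = 0.80, 0.89
        assert round(2 * p * r / (p + r), 2) == 0.84

    def test_contingency_hand_arithmetic(self):
        # 2-class outcome with TP=8, FP=2, FN=1 for class "pos"
        true = np.array(["pos"] * 9 + ["neg"] * 11)
        pred = np.array(["pos"] * 8 + ["neg"] + ["pos"] * 2 + ["neg"] * 9)
        rep = evaluate(pred, true)
        i = list(rep.classes).index("pos")
        assert np.isclose(rep.precision[i], 0.8)
        assert np.isclose(rep.recall[i], 8 / 9)

    def test_row_sums_equal_class_counts(self, rng):
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        rep = evaluate(pred, true)
        for i, c in enumerate(rep.classes):
            assert rep.confusion[i].sum() == np.sum(true == c)

    def test_macro_f1_invariant_under_relabeling(self, rng):
        true = rng.integers(0, 3, 100)
        pred = rng.integers(0, 3, 100)
        rep1 = evaluate(pred, true)
        relabel = {0: 2, 1: 0, 2: 1}
        rep2 = evaluate(
            np.vectorize(relabel.get)(pred), np.vectorize(relabel.get)(true)
        )
        assert np.isclose(rep1.macro_f1, rep2.macro_f1)
        assert np.isclose(rep1.accuracy, rep2.accuracy)

    def test_unseen_predicted_label_flagged(self):
        rep = evaluate(np.array(["a", "z"]), np.array(["a", "a"]))
        assert rep.extra_predicted == ["z"]
        assert rep.confusion.shape == (1, 2)

    def test_rmse_against_reference(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        true = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        scores = rng.normal(size=(50, 2))
        rep = evaluate(pred, true, scores, score_classes=np.array([0, 1]))
        T = np.where(true[:, None] == np.array([0, 1])[None, :], 1.0, -1.0)
        ref = np.sqrt(sk.mean_squared_error(T.ravel(), scores.ravel()))
        assert np.isclose(rep.rmse, ref)
        assert np.isclose(rep.accuracy, sk.accuracy_score(true, pred))
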