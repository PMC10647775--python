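"""The five predictors: fitting behavior, limits, and serialization."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

import cephgrowth as cg
from cephgrowth import models
from cephgrowth.errors import ConfigurationError, DataError, NumericalError

from conftest import as_dataset


def sklearn_adjusted_r2(X, y, cols):
    """Independent adjusted-R² oracle (sklearn OLS + textbook formula)."""
    n, k = len(y), len(cols)
    if k == 0:
        return 0.0
    r2 = LinearRegression().fit(X[:, cols], y).score(X[:, cols], y)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


class TestStepwise:
    def test_planted_single_feature_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 11))
        y = 2.0 * X[:, 3] + 1.0
        fit = models.fit_mra_stepwise(as_dataset(X, y), "t0")
        assert fit.selected == [3]
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.coef[3] == pytest.approx(2.0, abs=1e-10)

    def test_useless_candidates_give_intercept_only_model(self):
        # a constant feature can never improve adjusted R²
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        X = np.ones((6, 1))
        fit = models.fit_mra_stepwise(as_dataset(X, y), "t0")
        assert fit.selected == []
        np.testing.assert_allclose(fit.predict(X), np.full(6, y.mean()))

    def test_constant_target_intercept_only(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 4))
        fit = models.fit_mra_stepwise(as_dataset(X, np.full(10, 3.5)), "t0")
        assert fit.extras.get("constant_target")
        np.testing.assert_allclose(fit.predict(X), 3.5)

    def test_trace_matches_exhaustive_single_step_scan(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        beta = np.array([1.5, 0.0, -2.0, 0.0, 0.7, 0.0])
        y = X @ beta + 0.3 * rng.standard_normal(40)
        trace = []
        fit = models.fit_mra_stepwise(as_dataset(X, y), "t0", trace=trace)
        for step in trace:
            state = step["state"]
            if step["action"] == "add":
                cands = [c for c in range(6) if c not in state]
                scores = {c: sklearn_adjusted_r2(X, y, state + [c]) for c in cands}
            else:
                scores = {c: sklearn_adjusted_r2(X, y, [s for s in state if s != c]) for c in state}
            best = max(scores.values())
            assert scores[step["feature"]] == pytest.approx(best, abs=1e-12)
            assert step["adj_r2"] == pytest.approx(best, abs=1e-10)
        # terminal local optimality
        final = sklearn_adjusted_r2(X, y, fit.selected)
        for c in range(6):
            if c not in fit.selected:
                assert sklearn_adjusted_r2(X, y, fit.selected + [c]) <= final + 1e-12
        for c in fit.selected:
            others = [s for s in fit.selected if s != c]
            assert sklearn_adjusted_r2(X, y, others) <= final + 1e-12


class TestLasso:
    def test_full_shrinkage_above_critical_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 6))
        y = X[:, 0] + 0.1 * rng.standard_normal(25)
        lam_max = models.default_lambda_grid(X, y, n_lambdas=1, eps=1.0)[0]
        fit = models.fit_lasso(as_dataset(X, y), "t0", lambda_grid=[lam_max * 1.01])
        assert fit.selected == []
        np.testing.assert_allclose(fit.predict(X), y.mean(), atol=1e-10)

    def test_vanishing_penalty_matches_ols(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 8))
        beta = rng.standard_normal(8)
        y = X @ beta + 0.05 * rng.standard_normal(50)
        fit = models.fit_lasso(
            as_dataset(X, y), "t0", lambda_grid=[1e-10], tol=1e-14, max_iter=500_000
        )
        ols = LinearRegression().fit(X, y)
        np.testing.assert_allclose(fit.coef, ols.coef_, rtol=1e-6, atol=1e-8)
        assert fit.intercept == pytest.approx(ols.intercept_, abs=1e-6)

    def test_kkt_subgradient_conditions(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 5))
        y = X @ np.array([2.0, 0.0, -1.0, 0.0, 0.5]) + 0.2 * rng.standard_normal(30)
        ds = as_dataset(X, y)
        fit = models.fit_lasso(ds, "t0", inner_folds=3, n_lambdas=10, eps=1e-3, tol=1e-12)
        lam = fit.extras["lambda"]
        coef_std = np.asarray(fit.extras["coef_std"])
        mean = np.asarray(fit.extras["x_mean"])
        sd = np.asarray(fit.extras["x_sd"])
        Xs = (X - mean) / sd
        resid = y - fit.predict(X)
        g = Xs.T @ resid / len(y)  # gradient of (1/(2n))·RSS
        active = np.abs(coef_std) > 1e-10
        np.testing.assert_allclose(g[active], lam * np.sign(coef_std[active]), atol=1e-6)
        assert np.all(np.abs(g[~active]) <= lam + 1e-6)

    def test_support_size_monotone_along_penalty_grid(self):
        # orthogonal design: soft thresholding makes monotonicity exact
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 10)))
        X = Q * np.sqrt(40)
        y = X @ np.array([3.0, -2.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        y += 0.1 * rng.standard_normal(40)
        grid = models.default_lambda_grid(X, y, n_lambdas=12, eps=1e-4)
        sizes = [
            len(models.fit_lasso(as_dataset(X, y), "t0", lambda_grid=[lam]).selected)
            for lam in sorted(grid, reverse=True)
        ]
        assert sizes == sorted(sizes)

    def test_degenerate_grid_rejected(self):
        rng = np.random.default_rng(7)
        ds = as_dataset(rng.standard_normal((10, 3)), rng.standard_normal(10))
        with pytest.raises(ConfigurationError, match="lambda_grid"):
            models.fit_lasso(ds, "t0", lambda_grid=[])
        with pytest.raises(ConfigurationError, match="lambda_grid"):
            models.fit_lasso(ds, "t0", lambda_grid=[0.1, -0.5])


class TestRBFN:
    def test_flat_basis_limit_predicts_training_mean(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 3))
        y = rng.normal(5.0, 2.0, 30)
        fit = models.fit_rbfn(as_dataset(X, y), n_clusters=1, sigma=1e6, epochs=2000, seed=0)
        np.testing.assert_allclose(fit.predict(X)[:, 0], y.mean(), atol=1e-8)

    def test_planted_rbf_mixture_recovered(self):
        rng = np.random.default_rng(9)
        centroids = np.array([[2.0, 0.0, 0.0], [-2.0, 1.0, 0.0], [0.0, -2.0, 2.0]])
        labels = rng.integers(0, 3, 90)
        X = centroids[labels] + 0.25 * rng.standard_normal((90, 3))
        sigma, w = 1.2, np.array([3.0, -2.0, 1.5])
        F = np.exp(-((X[:, None, :] - centroids[None]) ** 2).sum(2) / (2 * sigma**2))
        noise_sd = 0.15
        y = F @ w + noise_sd * rng.standard_normal(90)
        fit = models.fit_rbfn(
            as_dataset(X, y), n_clusters=3, sigma=sigma, epochs=20_000, lr=1e-3, seed=1
        )
        rmse_train = np.sqrt(((fit.predict(X)[:, 0] - y) ** 2).mean())
        assert rmse_train < 2 * noise_sd

    def test_search_is_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 4))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(40)
        a = models.fit_rbfn(as_dataset(X, y), search_budget=5, seed=3, epochs=500)
        b = models.fit_rbfn(as_dataset(X, y), search_budget=5, seed=3, epochs=500)
        assert a.sigma == b.sigma and a.extras["n_clusters"] == b.extras["n_clusters"]
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_bad_budget_rejected(self):
        rng = np.random.default_rng(11)
        ds = as_dataset(rng.standard_normal((10, 2)), rng.standard_normal(10))
        with pytest.raises(ConfigurationError, match="search_budget"):
            models.fit_rbfn(ds, search_budget=0)

    def test_hand_set_single_centroid_forward_pass(self):
        fit = models.RBFNFit(
            method="RBFN", targets=["t0"], feature_names=["f0", "f1"],
            centroids=np.array([[1.0, 2.0]]), sigma=0.7, weights=np.array([[2.5]]),
            x_mean=np.zeros(2), x_sd=np.ones(2), y_mean=np.zeros(1), y_sd=np.ones(1),
        )
        x = np.array([[0.0, 0.0]])
        d2 = 1.0**2 + 2.0**2
        expected = 2.5 * np.exp(-d2 / (2 * 0.7**2))
        assert fit.predict(x)[0, 0] == pytest.approx(expected, abs=1e-15)


class TestMLP:
    def test_linear_target_is_learned(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 3))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * X[:, 2]
        fit = models.fit_mlp(as_dataset(X, y), epochs=3000, seed=2)
        rmse_train = np.sqrt(((fit.predict(X)[:, 0] - y) ** 2).mean())
        assert rmse_train < 0.01 * y.std()

    def test_zero_epochs_is_the_initial_forward_pass(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        fit = models.fit_mlp(as_dataset(X, y), epochs=0, seed=4)
        Xs = (X - fit.x_mean) / fit.x_sd
        h = Xs
        for W, b in zip(fit.weights[:-1], fit.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        manual = (h @ fit.weights[-1] + fit.biases[-1]) * fit.y_sd + fit.y_mean
        np.testing.assert_array_equal(fit.predict(X), manual)
        refit = models.fit_mlp(as_dataset(X, y), epochs=0, seed=4)
        np.testing.assert_array_equal(fit.predict(X), refit.predict(X))

    def test_hand_set_single_hidden_unit_composition(self):
        # out = v0 + v1 * relu(w0 + w . x), checked point by point
        fit = models.MLPFit(
            method="MLP", targets=["t0"], feature_names=["f0", "f1"],
            weights=[np.array([[1.5], [-2.0]]), np.array([[0.5]])],
            biases=[np.array([0.25]), np.array([-1.0])],
            x_mean=np.zeros(2), x_sd=np.ones(2), y_mean=np.zeros(1), y_sd=np.ones(1),
        )
        for x in ([1.0, 0.5], [-3.0, 2.0]):
            z = max(0.25 + 1.5 * x[0] - 2.0 * x[1], 0.0)
            expected = -1.0 + 0.5 * z
            assert fit.predict(np.array([x]))[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_divergence_reports_epoch_and_rate(self):
        rng = np.random.default_rng(14)
        ds = as_dataset(rng.standard_normal((30, 3)), rng.standard_normal(30))
        with pytest.raises(NumericalError, match="epoch"):
            models.fit_mlp(ds, epochs=50, seed=0, lr=1e6)


class TestGBDT:
    def test_constant_target_fit_exactly(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((40, 4))
        y = np.full(40, 7.5)
        fit = models.fit_gbdt(
            as_dataset(X, y), "t0",
            params={"learning_rate": 0.1, "num_leaves": 2, "min_child_samples": 2},
        )
        np.testing.assert_allclose(fit.predict(X), 7.5, atol=1e-12)

    def test_no_split_possible_predicts_training_mean(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        fit = models.fit_gbdt(
            as_dataset(X, y), "t0",
            params={"learning_rate": 0.1, "num_leaves": 2, "min_child_samples": 50,
                    "num_boost_round": 1},
        )
        np.testing.assert_allclose(fit.predict(X), y.mean(), atol=1e-7)

    def test_two_level_step_function_matches_two_leaf_tree(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((40, 4))
        y = np.where(X[:, 1] > 0, 5.0, -3.0)
        fit = models.fit_gbdt(
            as_dataset(X, y), "t0",
            params={"learning_rate": 0.5, "num_leaves": 2, "min_child_samples": 2,
                    "num_boost_round": 60},
        )
        # oracle: an exact two-leaf tree predicts each group's mean
        hand = np.where(X[:, 1] > 0, y[X[:, 1] > 0].mean(), y[X[:, 1] <= 0].mean())
        np.testing.assert_allclose(fit.predict(X), hand, atol=1e-6)

    def test_tuned_fit_is_deterministic(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] ** 2 + 0.2 * rng.standard_normal(40)
        a = models.fit_gbdt(as_dataset(X, y), "t0", tuner_budget=4, seed=5)
        b = models.fit_gbdt(as_dataset(X, y), "t0", tuner_budget=4, seed=5)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.params == b.params

    def test_bad_budget_rejected(self):
        rng = np.random.default_rng(19)
        ds = as_dataset(rng.standard_normal((10, 2)), rng.standard_normal(10))
        with pytest.raises(ConfigurationError, match="tuner_budget"):
            models.fit_gbdt(ds, "t0", tuner_budget=0)


class TestPredictAndSerialization:
    def test_schema_mismatch_names_first_bad_column(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((10, 3))
        fit = models.fit_lasso(as_dataset(X, X[:, 0]), "t0", lambda_grid=[0.1])
        with pytest.raises(DataError, match="column 1.*f1"):
            models.predict(fit, X, feature_names=["f0", "WRONG", "f2"])

    @pytest.mark.parametrize("method", ["MRA", "LASSO", "RBFN", "MLP", "GBDT"])
    def test_round_trip_predictions_bit_identical(self, method, tmp_path):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((30, 4))
        y = X[:, 0] - 0.5 * X[:, 2] + 0.1 * rng.standard_normal(30)
        ds = as_dataset(X, y)
        if method == "MRA":
            fit = models.fit_mra_stepwise(ds, "t0")
        elif method == "LASSO":
            fit = models.fit_lasso(ds, "t0", inner_folds=3, n_lambdas=8)
        elif method == "RBFN":
            fit = models.fit_rbfn(ds, n_clusters=3, sigma=1.0, epochs=500, seed=0)
        elif method == "MLP":
            fit = models.fit_mlp(ds, epochs=200, seed=0)
        else:
            fit = models.fit_gbdt(ds, "t0", tuner_budget=2, seed=0)
        path = tmp_path / "model.json"
        models.save_model(fit, path)
        loaded = models.load_model(path)
        np.testing.assert_array_equal(
            np.asarray(fit.predict(X)), np.asarray(loaded.predict(X))
        )
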