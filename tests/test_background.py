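"""Background GLM fitting and prediction."""

import numpy as np
import pytest

from driverfis import BackgroundModel, fit_glm, predict_bfis
from driverfis.simulate import default_beta, simulate_regression


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        y = 1.0 + 2.0 * x.ravel()
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = fit_glm(x, y)
        np.testing.assert_allclose(model.beta, [1.0, 2.0], atol=1e-10)
        assert model.sigma0 == pytest.approx(1e-8)  # floored

    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(3.0, 1.5, 200)
        model = fit_glm(np.empty((200, 0)), y)
        assert model.beta[0] == pytest.approx(y.mean())
        assert model.sigma0 == pytest.approx(y.std(ddof=0))  # ML divisor n

    def test_matches_statsmodels_ols(self, rng):
        """Cross-check the closed-form fit against an independent OLS route."""
        import statsmodels.api as sm

        X = rng.normal(size=(150, 4))
        y = 2.0 + X @ [1.0, -0.5, 0.3, 0.0] + rng.normal(0, 1.2, 150)
        model = fit_glm(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(model.beta, ref.params, atol=1e-8)
        assert model.sigma0 == pytest.approx(
            np.sqrt(ref.ssr / len(y)), abs=1e-10
        )

    def test_parameter_recovery_simulation(self):
        X, y, beta = simulate_regression(
            n_genes=3000, p_features=12, sigma0=2.0, seed=11
        )
        model = fit_glm(X, y)
        design = np.hstack([np.ones((len(y), 1)), X])
        se = 2.0 * np.sqrt(np.diag(np.linalg.inv(design.T @ design)))
        assert np.all(np.abs(model.beta - beta) < 3 * se)
        assert abs(model.sigma0 - 2.0) / 2.0 < 0.05

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.normal(size=(50, 2))
        X = np.hstack([X, X[:, [0]]])  # duplicate column
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(X, rng.normal(size=50), feature_names=["a", "b", "a_copy"])

    def test_too_few_genes(self, rng):
        with pytest.raises(ValueError, match="parameters"):
            fit_glm(rng.normal(size=(3, 4)), rng.normal(size=3))

    def test_unbiased_variance_flag(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        ml = fit_glm(X, y)
        ub = fit_glm(X, y, unbiased_variance=True)
        assert ub.sigma0 == pytest.approx(ml.sigma0 * np.sqrt(60 / (60 - 4)))


class TestPredict:
    def test_dot_product(self):
        m = BackgroundModel(np.array([1.0, 2.0]), 1.0, ("x1",), 10)
        assert predict_bfis(m, np.array([3.0])) == 7.0

    def test_zero_vector_gives_intercept(self):
        m = BackgroundModel(np.array([4.2, 2.0, -1.0]), 1.0, ("a", "b"), 10)
        assert predict_bfis(m, np.zeros(2)) == 4.2

    def test_training_predictions_match_fitted_values(self, rng):
        X = rng.normal(size=(80, 3))
        y = 1.0 + X @ [0.5, -1.0, 2.0] + rng.normal(0, 0.5, 80)
        model = fit_glm(X, y)
        design = np.hstack([np.ones((80, 1)), X])
        np.testing.assert_allclose(
            predict_bfis(model, X), design @ model.beta, atol=1e-10
        )

    def test_feature_name_mismatch(self):
        m = BackgroundModel(np.array([0.0, 1.0]), 1.0, ("x1",), 10)
        with pytest.raises(ValueError, match="feature names"):
            predict_bfis(m, np.array([1.0]), feature_names=["other"])


class TestProperties:
    def test_residual_orthogonality(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        model = fit_glm(X, y)
        design = np.hstack([np.ones((200, 1)), X])
        r = y - design @ model.beta
        assert np.max(np.abs(design.T @ r)) < 1e-8 * 200

    def test_refit_on_predictions_is_idempotent(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        model = fit_glm(X, y)
        yhat = predict_bfis(model, X)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            refit = fit_glm(X, yhat)
        np.testing.assert_allclose(refit.beta, model.beta, atol=1e-8)

    def test_coefficient_interval_coverage(self):
        """95% normal-theory intervals cover the truth at the nominal rate."""
        from scipy.stats import norm

        beta = default_beta(3)
        z = norm.ppf(0.975)
        covered = np.zeros(len(beta))
        reps = 500
        for rep in range(reps):
            X, y, _ = simulate_regression(
                n_genes=120, p_features=3, beta=beta, sigma0=1.5, seed=rep
            )
            model = fit_glm(X, y, unbiased_variance=True)
            design = np.hstack([np.ones((120, 1)), X])
            se = model.sigma0 * np.sqrt(np.diag(np.linalg.inv(design.T @ design)))
            covered += np.abs(model.beta - beta) <= z * se
        coverage = covered / reps
        assert np.all(np.abs(coverage - 0.95) <= 0.03)


def test_save_load_round_trip(tmp_path, rng):
    X = rng.normal(size=(50, 2))
    model = fit_glm(X, rng.normal(size=50), feature_names=["a", "b"])
    path = tmp_path / "model.json"
    model.save(path)
    loaded = BackgroundModel.load(path)
    np.testing.assert_array_equal(loaded.beta, model.beta)
    assert loaded.sigma0 == model.sigma0
    assert loaded.feature_names == model.feature_names
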