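"""LASSO path: closed forms, KKT conditions, and an independent convex oracle.

The oracle minimizes the same objective, (1/2n)||y - b0 - X beta||^2 +
lambda*||beta||_1, with scipy's L-BFGS-B on the split formulation
beta = beta_plus - beta_minus (both >= 0), which is smooth with bound
constraints — a completely different algorithm from coordinate descent.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from crossmir import (
    ExpressionMatrix,
    fit_lasso_path,
    fit_lasso_per_mirna,
    lambda_path,
    lasso_objective,
    predict_lasso,
)
from crossmir.lasso import kkt_violation, _standardize


def oracle_lasso(X, y, lam):
    """Independent solver: L-BFGS-B on the split-variable formulation."""
    n, p = X.shape
    Xs, x_mean, x_sd = _standardize(X)
    y_mean = y.mean()
    yc = y - y_mean

    def fun(u):
        beta = u[:p] - u[p:]
        r = yc - Xs @ beta
        grad_beta = -(Xs.T @ r) / n
        f = r @ r / (2 * n) + lam * u.sum()
        return f, np.concatenate([grad_beta + lam, -grad_beta + lam])

    res = minimize(
        fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta_std = res.x[:p] - res.x[p:]
    beta = beta_std / x_sd
    b0 = y_mean - beta @ x_mean
    return beta, b0


class TestLambdaPath:
    def test_orthonormal_fixture_lambda_max_is_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])  # standardized: mean 0, sd 1
        X = y.reshape(-1, 1)
        lams = lambda_path(X, y, nlambda=5)
        assert lams[0] == pytest.approx(1.0, abs=1e-12)

    def test_log_spacing_three_points(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = y.reshape(-1, 1)
        lams = lambda_path(X, y, nlambda=3, ratio=0.01)
        np.testing.assert_allclose(lams, [1.0, 0.1, 0.01], rtol=1e-12)

    @pytest.mark.parametrize("nlambda", [2, 10, 100])
    def test_length_and_strictly_decreasing(self, nlambda):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 6))
        Xs, _, _ = _standardize(X)
        y = rng.normal(size=15)
        lams = lambda_path(Xs, y - y.mean(), nlambda=nlambda)
        assert len(lams) == nlambda
        assert np.all(np.diff(lams) < 0)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        Xs, _, _ = _standardize(X)
        with pytest.raises(ValueError, match="degenerate response"):
            lambda_path(Xs, np.zeros(10))


class TestFitLassoPath:
    def test_at_lambda_max_all_zero_intercept_is_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20) + 3.0
        path = fit_lasso_path(X, y, nlambda=30)
        first = np.asarray(path.coefs.getrow(0).todense()).ravel()
        assert np.all(first == 0.0)
        assert path.intercepts[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_orthonormal_design_soft_threshold_closed_form(self):
        # orthonormal standardized design: beta_j(lam) = soft(beta_ols_j, lam).
        # QR of a column-centered matrix keeps column means at 0, so scaling
        # Q by sqrt(n) gives mean-0, sd-1 columns orthonormal under <.,.>/n.
        rng = np.random.default_rng(3)
        n, p = 64, 4
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = Q * np.sqrt(n)
        y = rng.normal(size=n)
        yc = y - y.mean()
        beta_ols = X.T @ yc / n
        lams = np.max(np.abs(beta_ols)) * np.array([0.9, 0.6, 0.3, 0.05])
        path = fit_lasso_path(X, y, lambdas=lams)
        for k, lam in enumerate(lams):
            expected = np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0)
            got = np.asarray(path.coefs.getrow(k).todense()).ravel()
            np.testing.assert_allclose(got, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        p = int(rng.integers(3, 51))
        X = rng.normal(size=(n, p))
        beta_true = np.zeros(p)
        beta_true[: min(3, p)] = rng.normal(size=min(3, p))
        y = X @ beta_true + 0.3 * rng.normal(size=n)
        path = fit_lasso_path(X, y, nlambda=8, ratio=0.05)
        for k in (3, 7):
            lam = path.lambdas[k]
            beta_cd = np.asarray(path.coefs.getrow(k).todense()).ravel()
            b0_cd = path.intercepts[k]
            beta_or, b0_or = oracle_lasso(X, y, lam)
            f_cd = objective_original_scale(X, y, beta_cd, b0_cd, lam)
            f_or = objective_original_scale(X, y, beta_or, b0_or, lam)
            assert abs(f_cd - f_or) < 1e-6

    def test_kkt_along_path(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 40))
        y = X[:, 0] - 2 * X[:, 5] + 0.2 * rng.normal(size=25)
        path = fit_lasso_path(X, y, nlambda=20)
        assert kkt_violation(path, X, y) < 1e-6

    def test_training_mse_non_increasing_in_decreasing_lambda(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=30)
        path = fit_lasso_path(X, y, nlambda=25)
        mses = [np.mean((y - path.predict(X, k)) ** 2) for k in range(path.nlambda)]
        assert np.all(np.diff(mses) <= 1e-10)

    def test_non_finite_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso_path(X, np.arange(5.0))


def objective_original_scale(X, y, beta, b0, lam):
    """The fitted objective expressed in original-scale coefficients.

    The L1 penalty applies to the standardized coefficients, i.e. to
    ``beta * sd(x_j)``; the residual term is scale-free.
    """
    X = np.asarray(X, float)
    _, _, x_sd = _standardize(X)
    n = X.shape[0]
    r = y - b0 - X @ beta
    return float(r @ r / (2 * n) + lam * np.sum(np.abs(beta * x_sd)))


class TestPerMirna:
    def _paired(self, n=12, p=15, n_mirna=5, seed=0):
        rng = np.random.default_rng(seed)
        X = ExpressionMatrix([f"g{i}" for i in range(p)], [f"s{j}" for j in range(n)],
                             rng.uniform(0, 1, size=(p, n)), "compressed")
        Y = ExpressionMatrix([f"m{i}" for i in range(n_mirna)], [f"s{j}" for j in range(n)],
                             rng.uniform(0, 1, size=(n_mirna, n)), "compressed")
        return X, Y

    def test_one_path_per_mirna(self):
        X, Y = self._paired()
        models = fit_lasso_per_mirna(X, Y, nlambda=12)
        assert sorted(models.paths) == sorted(Y.feature_ids)

    def test_constant_mirna_recorded_as_skipped(self):
        X, Y = self._paired()
        Y.values[2, :] = 0.7
        models = fit_lasso_per_mirna(X, Y, nlambda=12)
        assert len(models.paths) == 4
        assert models.skipped == {"m2": pytest.approx(0.7)}

    def test_predict_choices(self):
        X, Y = self._paired(n=20, seed=4)
        models = fit_lasso_per_mirna(X, Y, nlambda=100)
        p_min = predict_lasso(models, X, "minimal")
        p_10 = predict_lasso(models, X, "tenth_largest")
        # training error is monotone in lambda: minimal-lambda fit is tighter
        mse_min = np.mean((p_min.values - Y.values) ** 2)
        mse_10 = np.mean((p_10.values - Y.values) ** 2)
        assert mse_min <= mse_10
        # tenth_largest uses the 10th entry of each decreasing path
        path = models.paths["m0"]
        expected = path.predict(X.values.T, 9)
        np.testing.assert_allclose(p_10.values[0], expected, atol=1e-12)

    def test_tenth_largest_needs_10_lambdas(self):
        X, Y = self._paired()
        models = fit_lasso_per_mirna(X, Y, nlambda=5)
        with pytest.raises(ValueError, match="10"):
            predict_lasso(models, X, "tenth_largest")

    def test_skipped_mirna_predicts_training_mean(self):
        X, Y = self._paired()
        Y.values[0, :] = 0.25
        models = fit_lasso_per_mirna(X, Y, nlambda=12)
        pred = predict_lasso(models, X, "minimal")
        row = pred.feature_ids.index("m0")
        np.testing.assert_allclose(pred.values[row], 0.25, atol=1e-12)

    def test_recovery_on_linear_synthetic(self):
        # miRNA = sparse linear function of mRNA: minimal-lambda training
        # predictions should track the truth sample-wise
        rng = np.random.default_rng(9)
        n, p, m = 30, 40, 6
        Xv = rng.uniform(0, 1, size=(p, n))
        W = np.zeros((m, p))
        for i in range(m):
            W[i, rng.choice(p, 3, replace=False)] = rng.normal(0, 1, 3)
        Yv = W @ Xv + 0.01 * rng.normal(size=(m, n))
        X = ExpressionMatrix([f"g{i}" for i in range(p)], [f"s{j}" for j in range(n)], Xv, "compressed")
        Y = ExpressionMatrix([f"m{i}" for i in range(m)], [f"s{j}" for j in range(n)], Yv, "compressed")
        models = fit_lasso_per_mirna(X, Y)
        pred = predict_lasso(models, X, "minimal")
        rs = [np.corrcoef(pred.values[:, j], Y.values[:, j])[0, 1] for j in range(n)]
        assert np.median(rs) >= 0.9
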