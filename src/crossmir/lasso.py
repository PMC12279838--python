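"""Per-miRNA LASSO regression along an automatically generated lambda path.

For each miRNA, a sparse linear model predicts its expression from the full
mRNA matrix by minimizing, on the standardized predictor scale,

    (1 / 2n) * ||y - b0 - X beta||^2 + lambda * ||beta||_1

by cyclic coordinate descent with soft-thresholding, warm-started along a
strictly decreasing lambda path. The path runs from lambda_max — the
smallest penalty at which every coefficient is zero, max_j |<x_j, y>| / n —
log-equispaced down to lambda_max * ratio. No cross-validation is performed;
predictions are taken either at the smallest path value ("minimal", lowest
training MSE, strongest overfitting risk) or at the 10th-largest value
("tenth_largest", heavier regularization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

CONVERGENCE_TOL = 1e-7  # max absolute coefficient change per sweep
MAX_SWEEPS = 10_000


def lambda_path(
    X: np.ndarray, y: np.ndarray, nlambda: int = 100, ratio: float = 0.01
) -> np.ndarray:
    """Decreasing log-equispaced penalties from lambda_max to lambda_max*ratio.

    ``X`` must be standardized (mean 0, sd 1 per column, 1/n convention) and
    ``y`` centered; ``n`` is the sample count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        raise ValueError("degenerate response: lambda_max is 0 (constant y or no signal)")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), nlambda)


@njit(cache=True)
def _cd_path(Xs, y, lambdas, tol, max_sweeps):  # pragma: no cover - jitted
    """Cyclic coordinate descent over a decreasing lambda path.

    Columns of Xs are standardized so each coordinate update is a plain
    soft-threshold. Warm starts across path points; after a full sweep,
    iterates only over the active set until converged, then re-checks with
    another full sweep (the glmnet strategy).
    """
    n, p = Xs.shape
    nl = lambdas.shape[0]
    betas = np.zeros((nl, p))
    beta = np.zeros(p)
    r = y.copy()
    for k in range(nl):
        lam = lambdas[k]
        for _outer in range(max_sweeps):
            # full sweep over all predictors
            max_change = 0.0
            for j in range(p):
                bj = beta[j]
                rho = 0.0
                for i in range(n):
                    rho += Xs[i, j] * r[i]
                z = rho / n + bj
                az = abs(z) - lam
                nb = 0.0
                if az > 0.0:
                    nb = az if z > 0.0 else -az
                dlt = nb - bj
                if dlt != 0.0:
                    for i in range(n):
                        r[i] -= Xs[i, j] * dlt
                    beta[j] = nb
                    if abs(dlt) > max_change:
                        max_change = abs(dlt)
            if max_change < tol:
                break
            # active-set sweeps until converged
            active = np.nonzero(beta)[0]
            for _inner in range(max_sweeps):
                max_change_a = 0.0
                for a in range(active.shape[0]):
                    j = active[a]
                    bj = beta[j]
                    rho = 0.0
                    for i in range(n):
                        rho += Xs[i, j] * r[i]
                    z = rho / n + bj
                    az = abs(z) - lam
                    nb = 0.0
                    if az > 0.0:
                        nb = az if z > 0.0 else -az
                    dlt = nb - bj
                    if dlt != 0.0:
                        for i in range(n):
                            r[i] -= Xs[i, j] * dlt
                        beta[j] = nb
                        if abs(dlt) > max_change_a:
                            max_change_a = abs(dlt)
                if max_change_a < tol:
                    break
        betas[k] = beta
    return betas


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/n convention, as in glmnet
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


@dataclass
class LassoPath:
    """One miRNA's fitted path: coefficients on the original predictor scale."""

    lambdas: np.ndarray
    coefs: sparse.csr_matrix          # nlambda x p, original scale
    intercepts: np.ndarray            # nlambda
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float

    @property
    def nlambda(self) -> int:
        return len(self.lambdas)

    def predict(self, X: np.ndarray, index: int) -> np.ndarray:
        """Predict responses for samples-x-predictors ``X`` at path point ``index``."""
        coef = np.asarray(self.coefs.getrow(index).todense()).ravel()
        return X @ coef + self.intercepts[index]


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    nlambda: int = 100,
    ratio: float = 0.01,
    lambdas: np.ndarray | None = None,
) -> LassoPath:
    """Fit the full coordinate-descent path for one response.

    ``X`` is samples x predictors on its original scale (standardization is
    internal); p >> n is expected. Coefficients are returned de-standardized
    and the intercept absorbs the centering, so ``predict`` works on raw
    predictor values.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in predictors or response")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    Xs, x_mean, x_sd = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    if lambdas is None:
        lambdas = lambda_path(Xs, yc, nlambda=nlambda, ratio=ratio)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")

    betas_std = _cd_path(Xs, yc, lambdas, CONVERGENCE_TOL, MAX_SWEEPS)
    # snap float-epsilon activations (|z| - lambda ~ 1 ulp at lambda_max) to 0
    betas_std[np.abs(betas_std) < 1e-10] = 0.0
    betas = betas_std / x_sd[None, :]
    intercepts = y_mean - betas @ x_mean
    return LassoPath(
        lambdas=lambdas,
        coefs=sparse.csr_matrix(betas),
        intercepts=intercepts,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
    )


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float, lam: float) -> float:
    """(1/2n)||y - b0 - X beta||^2 + lam ||beta||_1 — for oracle comparisons."""
    n = X.shape[0]
    resid = y - b0 - X @ beta
    return float(resid @ resid / (2 * n) + lam * np.sum(np.abs(beta)))


def kkt_violation(path: LassoPath, X: np.ndarray, y: np.ndarray) -> float:
    """Largest KKT violation over all path points (0 for an exact solution).

    At optimum, on the standardized scale: |<x_j, r>|/n <= lambda for every
    inactive j and = lambda for every active j.
    """
    Xs = (np.asarray(X, dtype=float) - path.x_mean) / path.x_sd
    yc = np.asarray(y, dtype=float) - path.y_mean
    worst = 0.0
    betas_std = np.asarray(path.coefs.todense()) * path.x_sd[None, :]
    n = Xs.shape[0]
    for k, lam in enumerate(path.lambdas):
        b = np.asarray(betas_std[k]).ravel()
        r = yc - Xs @ b
        g = np.abs(Xs.T @ r) / n
        inactive = b == 0
        if inactive.any():
            worst = max(worst, float(np.max(g[inactive] - lam, initial=0.0)))
        if (~inactive).any():
            worst = max(worst, float(np.max(np.abs(g[~inactive] - lam))))
    return worst


@dataclass
class LassoModelSet:
    """One LassoPath per miRNA plus the shared predictor space."""

    predictor_ids: list[str]
    paths: dict[str, LassoPath] = field(default_factory=dict)
    skipped: dict[str, float] = field(default_factory=dict)  # miRNA -> training mean
    nlambda: int = 100

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.paths) + list(self.skipped)


def fit_lasso_per_mirna(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    nlambda: int = 100,
    ratio: float = 0.01,
) -> LassoModelSet:
    """Fit an individual lambda path for every miRNA row of ``Y``.

    miRNAs with a degenerate (constant / zero-signal) response are recorded
    as skipped with their training mean rather than aborting the run.
    """
    if X.sample_ids != Y.sample_ids:
        raise ValueError("mRNA and miRNA matrices must share samples in order")
    Xt = np.ascontiguousarray(X.values.T)
    models = LassoModelSet(predictor_ids=list(X.feature_ids), nlambda=nlambda)
    for g, mirna in enumerate(Y.feature_ids):
        y = Y.values[g, :]
        try:
            models.paths[mirna] = fit_lasso_path(Xt, y, nlambda=nlambda, ratio=ratio)
        except ValueError as exc:
            if "degenerate response" not in str(exc):
                raise
            models.skipped[mirna] = float(y.mean())
    if models.skipped:
        logger.info("lasso: skipped %d degenerate miRNA response(s)", len(models.skipped))
    return models


def predict_lasso(
    models: LassoModelSet, X: ExpressionMatrix, lambda_choice: str = "minimal"
) -> ExpressionMatrix:
    """Predict a miRNA matrix at a chosen point of every path.

    ``minimal`` uses each path's last (smallest) lambda; ``tenth_largest``
    uses the 10th entry of the decreasing path (index 9). Skipped miRNAs
    predict as their training mean.
    """
    if X.feature_ids != models.predictor_ids:
        raise ValueError("predictor features do not match the fitted model set")
    if lambda_choice not in ("minimal", "tenth_largest"):
        raise ValueError("lambda_choice must be 'minimal' or 'tenth_largest'")
    Xt = X.values.T
    mirna_ids = models.mirna_ids
    out = np.empty((len(mirna_ids), X.n_samples))
    for i, mirna in enumerate(mirna_ids):
        if mirna in models.skipped:
            out[i, :] = models.skipped[mirna]
            continue
        path = models.paths[mirna]
        if lambda_choice == "tenth_largest":
            if path.nlambda < 10:
                raise ValueError(
                    f"path for {mirna} has {path.nlambda} < 10 lambdas; "
                    "cannot take the 10th largest"
                )
            idx = 9
        else:
            idx = path.nlambda - 1
        out[i, :] = path.predict(Xt, idx)
    return ExpressionMatrix(
        feature_ids=mirna_ids,
        sample_ids=list(X.sample_ids),
        values=out,
        scale_tag=X.scale_tag,
    )
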