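"""Two-group differential expression with empirical-Bayes variance moderation.

Per feature g the statistic is a two-sample t whose pooled residual variance
s_g^2 (d = n1 + n2 - 2 df) is shrunk toward a prior variance s0^2 carrying
d0 prior degrees of freedom:

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g    = (mean_diseased - mean_control) / (s~_g * sqrt(1/n1 + 1/n2))

and the two-sided p-value uses d + d0 degrees of freedom. The prior (d0,
s0^2) is estimated by the method of moments on e_g = log s_g^2 -
digamma(d/2) + log(d/2): d0 solves trigamma(d0/2) = var(e) - trigamma(d/2)
(monotone in d0; d0 = +inf when the right-hand side is <= 0, i.e. the
observed variances scatter no more than sampling alone explains), and
log s0^2 = mean(e) + digamma(d0/2) - log(d0/2).

No multiple-testing adjustment is applied anywhere: downstream concordance
metrics correlate the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix, SampleGroups


@dataclass
class DEAResult:
    feature_ids: list[str]
    logfc: np.ndarray          # diseased minus control mean, analysis scale
    moderated_t: np.ndarray
    p_raw: np.ndarray          # two-sided, unadjusted
    d0: float                  # prior degrees of freedom (may be +inf)
    s0_sq: float               # prior variance
    residual_df: float         # d = n1 + n2 - 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "logFC": self.logfc,
             "t": self.moderated_t, "P.Value": self.p_raw}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, monotone)."""
    if y <= 0:
        raise ValueError("trigamma is positive; no solution for y <= 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from residual variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        # not enough information to estimate a spread: no moderation
        s0 = float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 0.0
        return np.inf, s0
    e = np.log(s2[ok]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    rhs = var_e - float(special.polygamma(1, d / 2.0))
    if rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(mean_e))
    else:
        d0 = 2.0 * trigamma_inverse(rhs)
        s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    X: ExpressionMatrix,
    groups: SampleGroups,
    d0_override: float | None = None,
    s0_sq_override: float | None = None,
) -> DEAResult:
    """Moderated two-group t-test on every feature of ``X``.

    ``d0_override``/``s0_sq_override`` bypass the empirical-Bayes fit
    (``d0_override=0`` recovers the ordinary pooled two-sample t-test).
    Both groups need at least two samples.
    """
    groups.validate_against(X, require_two_per_group=True)
    cond = np.array([groups.condition_of(s) for s in X.sample_ids])
    ctrl = X.values[:, cond == "control"]
    dis = X.values[:, cond == "diseased"]
    n1, n2 = ctrl.shape[1], dis.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")

    logfc = dis.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (dis - dis.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(s0_sq_override) if s0_sq_override is not None else 0.0
    else:
        d0, s0_sq = _fit_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return DEAResult(
        feature_ids=list(X.feature_ids),
        logfc=logfc,
        moderated_t=t,
        p_raw=p,
        d0=d0,
        s0_sq=s0_sq,
        residual_df=float(d),
    )


def run_dea_pair(
    Y_true: ExpressionMatrix, Y_pred: ExpressionMatrix, groups: SampleGroups
) -> tuple[DEAResult, DEAResult]:
    """Moderated t-test on the true and the predicted miRNA matrices.

    Both analyses run independently on the same scale, so the downstream
    log-fold-change and p-value correlations compare like with like.
    """
    if Y_true.feature_ids != Y_pred.feature_ids:
        raise ValueError("true and predicted matrices must share feature IDs and order")
    if Y_true.sample_ids != Y_pred.sample_ids:
        raise ValueError("true and predicted matrices must share sample IDs and order")
    return moderated_t_test(Y_true, groups), moderated_t_test(Y_pred, groups)
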