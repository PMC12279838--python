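"""Concordance between true and predicted miRNA data.

Three levels, all Pearson correlations: per-sample profile correlation
across features, correlation of the two log-fold-change vectors, and
correlation of the two raw p-value vectors from differential expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dea import DEAResult
from .matrix import ExpressionMatrix


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def samplewise_correlation(Y_true: ExpressionMatrix, Y_pred: ExpressionMatrix) -> np.ndarray:
    """Per-sample Pearson r across features; NaN where a column is constant."""
    if Y_true.shape != Y_pred.shape:
        raise ValueError("matched shapes required")
    out = np.full(Y_true.n_samples, np.nan)
    for j in range(Y_true.n_samples):
        a, b = Y_true.values[:, j], Y_pred.values[:, j]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue  # undefined; recorded as missing
        out[j] = stats.pearsonr(a, b).statistic
    return out


def dea_concordance(
    dea_true: DEAResult, dea_pred: DEAResult, neglog10_p: bool = False
) -> tuple[float, float]:
    """Correlate log-fold changes and (raw) p-values of the paired analyses.

    Features with a non-finite statistic in either result are dropped
    pairwise. ``neglog10_p`` correlates -log10(p) instead of raw p.
    """
    if dea_true.feature_ids != dea_pred.feature_ids:
        raise ValueError("DEA results must cover the same features in the same order")
    lt, lp = dea_true.logfc, dea_pred.logfc
    pt, pp = dea_true.p_raw, dea_pred.p_raw
    if neglog10_p:
        pt, pp = -np.log10(pt), -np.log10(pp)
    ok_l = np.isfinite(lt) & np.isfinite(lp)
    ok_p = np.isfinite(pt) & np.isfinite(pp)
    r_logfc = pearson(lt[ok_l], lp[ok_l])
    r_pvalue = pearson(pt[ok_p], pp[ok_p])
    return r_logfc, r_pvalue


@dataclass
class ConcordanceReport:
    """Everything a run reports about true-vs-predicted agreement."""

    sample_ids: list[str]
    per_sample_r: list[float]
    median_sample_r: float
    r_logfc: float
    r_pvalue: float
    n_features_compared: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ConcordanceReport":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        return cls(**data)

    def per_sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "r": self.per_sample_r})


def build_report(
    Y_true: ExpressionMatrix,
    Y_pred: ExpressionMatrix,
    dea_true: DEAResult,
    dea_pred: DEAResult,
    metadata: dict | None = None,
) -> ConcordanceReport:
    per_sample = samplewise_correlation(Y_true, Y_pred)
    r_logfc, r_pvalue = dea_concordance(dea_true, dea_pred)
    finite = per_sample[np.isfinite(per_sample)]
    return ConcordanceReport(
        sample_ids=list(Y_true.sample_ids),
        per_sample_r=[float(v) for v in per_sample],
        median_sample_r=float(np.median(finite)) if finite.size else float("nan"),
        r_logfc=r_logfc,
        r_pvalue=r_pvalue,
        n_features_compared=Y_true.n_features,
        metadata=metadata or {},
    )
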