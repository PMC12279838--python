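"""Normalization and scaling applied before model training.

The chain used on real data is: (counts only) voom-style log-CPM ->
quantile normalization -> global [0, 1] compression, optionally preceded by
removal of the lowest-expressed features. Compression puts predictor and
response matrices on one bounded scale so that a fixed augmentation noise
level (sd 0.01) and the network's loss are comparable across datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force all sample columns to share one empirical distribution.

    Each column's values are replaced by the reference quantiles — the
    across-column means of the column-sorted values — at their rank
    positions. Ties within a column receive the mean of the reference
    values their rank range spans (the standard convention).
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    v = X.values
    order = np.argsort(v, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(v, order, axis=0), axis=1)

    out = np.empty_like(v)
    n = v.shape[0]
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[idx[k + 1]] == col[idx[i]]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[idx, j] = assigned
    return X.with_values(out)


def voom_logcpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2 counts-per-million with the voom offsets.

    ``log2((count + 0.5) / (libsize + 1) * 1e6)`` where libsize is the
    column sum. Precision weights are not computed; only the transform is
    applied (downstream models are unweighted).
    """
    if counts.scale_tag != "counts":
        raise ValueError(f"expected scale_tag 'counts', got {counts.scale_tag!r}")
    v = counts.values
    if np.any(v < 0):
        raise ValueError("negative counts")
    libsize = v.sum(axis=0)
    out = np.log2((v + 0.5) / (libsize + 1.0) * 1e6)
    return X_with_tag(counts, out, "log_intensity")


def X_with_tag(X: ExpressionMatrix, values: np.ndarray, tag: str) -> ExpressionMatrix:
    return ExpressionMatrix(
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
        values=values,
        scale_tag=tag,
    )


@dataclass
class CompressionParams:
    """Matrix-wide (or per-feature) min/max used to rescale into [0, 1]."""

    global_min: float | np.ndarray
    global_max: float | np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.global_max) > np.asarray(self.global_min)):
            raise ValueError("global_max must exceed global_min")


def fit_compression(
    X: ExpressionMatrix, per_feature: bool = False, label: str = ""
) -> CompressionParams:
    """Record the min/max needed to map a matrix into [0, 1].

    Global (one min/max over all entries) by default, which preserves the
    relative expression levels across features; ``per_feature`` rescales
    each row independently instead.
    """
    v = X.values
    if per_feature:
        lo, hi = v.min(axis=1), v.max(axis=1)
        if np.any(hi == lo):
            raise ValueError("constant feature row(s): nothing to compress")
    else:
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            raise ValueError("constant matrix: nothing to compress")
    return CompressionParams(global_min=lo, global_max=hi, fitted_on=label or "unnamed")


def apply_compression(
    X: ExpressionMatrix, params: CompressionParams
) -> tuple[ExpressionMatrix, int]:
    """Rescale to (value - min) / (max - min), clipping to [0, 1].

    Values can fall outside [0, 1] when the params were fitted on another
    dataset (cross-study); those are clipped and counted. Returns the
    compressed matrix and the number of clipped entries.
    """
    lo = np.asarray(params.global_min)
    hi = np.asarray(params.global_max)
    if lo.ndim == 1:
        lo, hi = lo[:, None], hi[:, None]
    scaled = (X.values - lo) / (hi - lo)
    n_clipped = int(np.sum((scaled < 0) | (scaled > 1)))
    if n_clipped:
        logger.info(
            "compression: clipped %d entries outside [0,1] (params fitted on %s)",
            n_clipped, params.fitted_on,
        )
        scaled = np.clip(scaled, 0.0, 1.0)
    return X_with_tag(X, scaled, "compressed"), n_clipped


def filter_low_expressed(X: ExpressionMatrix, fraction: float = 0.2) -> ExpressionMatrix:
    """Drop the ``floor(fraction * n)`` features with the lowest mean expression.

    Survivors keep their input order. Ties at the cut mean are broken by
    input order: the earlier feature is removed first.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n = X.n_features
    k = math.floor(fraction * n)
    if k == 0:
        return X
    if k >= n:
        raise ValueError("fraction would remove every feature")
    means = X.values.mean(axis=1)
    drop = set(np.argsort(means, kind="stable")[:k])
    keep = [f for i, f in enumerate(X.feature_ids) if i not in drop]
    logger.info("expression filter: removed %d of %d features (fraction %.2f)", k, n, fraction)
    return X.select_features(keep)
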