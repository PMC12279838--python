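"""First-layer weight interpretability for trained networks.

For each mRNA input, the mean absolute weight with which it is forwarded to
the first hidden layer ranks its overall influence; the proportion of
transcription factors among the top-ranked inputs is compared with the
background proportion among all inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mlp import TrainedPredictor


def first_layer_mean_weights(
    model: TrainedPredictor, absolute: bool = True
) -> np.ndarray:
    """Per-input mean (absolute) first-layer weight.

    Absolute values are the default: signed means of a wide fan-out cancel
    toward zero and would rank noise. ``absolute=False`` gives the raw
    signed mean for comparison.
    """
    W = model.first_layer_weights  # raises for non-MLP predictors
    return np.abs(W).mean(axis=1) if absolute else W.mean(axis=1)


@dataclass
class WeightReport:
    feature_ids: list[str]
    per_input_mean_weight: list[float]
    top_fraction: float
    top_feature_ids: list[str]
    tf_prop_top: float
    tf_prop_all: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        in_top = set(self.top_feature_ids)
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mean_weight": self.per_input_mean_weight,
                "in_top": [f in in_top for f in self.feature_ids],
            }
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(asdict(self), indent=2))


def tf_enrichment(
    weights: np.ndarray,
    feature_ids: list[str],
    tf_list: set[str],
    top_fraction: float = 0.05,
) -> WeightReport:
    """Proportion of transcription factors among the highest-weight inputs.

    The top set holds the ``ceil(top_fraction * n)`` features with the
    largest mean weight; ties are broken by input order. TF membership is a
    case-insensitive match of feature IDs against the TF symbol list.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(feature_ids):
        raise ValueError("weights and feature_ids must align")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n = len(feature_ids)
    k = math.ceil(top_fraction * n)
    # stable sort on negated weights keeps input order among ties
    top_idx = np.argsort(-weights, kind="stable")[:k]
    top_ids = [feature_ids[i] for i in top_idx]

    tf_fold = {t.upper() for t in tf_list}
    is_tf = [f.upper() in tf_fold for f in feature_ids]
    tf_prop_all = sum(is_tf) / n if n else 0.0
    tf_prop_top = sum(feature_ids[i].upper() in tf_fold for i in top_idx) / k if k else 0.0

    return WeightReport(
        feature_ids=list(feature_ids),
        per_input_mean_weight=[float(w) for w in weights],
        top_fraction=top_fraction,
        top_feature_ids=top_ids,
        tf_prop_top=float(tf_prop_top),
        tf_prop_all=float(tf_prop_all),
    )


def analyze_first_layer(
    model: TrainedPredictor, tf_list: set[str], top_fraction: float = 0.05
) -> WeightReport:
    """Convenience wrapper: mean-absolute weights then TF enrichment."""
    w = first_layer_mean_weights(model)
    return tf_enrichment(w, model.input_feature_ids, tf_list, top_fraction=top_fraction)
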