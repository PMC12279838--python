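"""Gaussian-noise data augmentation for small paired training cohorts.

Whole-cohort noisy copies are appended, round by round, until every group
reaches the target size. Noise is i.i.d. Gaussian with a small standard
deviation (default 0.01) on the compressed [0, 1] scale; paired mRNA/miRNA
samples receive independent noise draws but stay paired under a shared new
sample ID. Originals are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix, SampleGroups


@dataclass
class AugmentConfig:
    noise_sd: float = 0.01
    min_samples: int = 100
    per_group: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def _rounds_needed(group_sizes: list[int], min_samples: int, per_group: bool) -> int:
    """Total rounds (originals count as round 1) so every unit reaches the target."""
    if per_group:
        return max(math.ceil(min_samples / n) for n in group_sizes)
    return math.ceil(min_samples / sum(group_sizes))


def augment_gaussian(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    groups: SampleGroups,
    cfg: AugmentConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleGroups]:
    """Append noisy whole-cohort copies until each group has >= min_samples.

    With ``per_group`` (the default) the target applies to the control and
    diseased groups separately, so condition-specific models also see enough
    samples. A cohort of 10 with the default target of 100 yields the 10
    originals plus 9 noisy copies of each. Values pushed outside [0, 1] by
    the noise are left as-is. Fully determined by ``cfg.seed``.
    """
    if X.sample_ids != Y.sample_ids:
        raise ValueError("X and Y must share sample IDs and order")
    groups.validate_against(X)
    sizes = [n for n in groups.group_sizes().values() if n > 0]
    present = [c for c, n in groups.group_sizes().items() if n > 0]
    if not sizes or (cfg.per_group and len(present) < 2):
        raise ValueError("both groups must be non-empty for per-group augmentation")

    rounds = _rounds_needed(sizes, cfg.min_samples, cfg.per_group)
    if rounds <= 1:
        return X, Y, groups

    rng = np.random.default_rng(cfg.seed)
    x_blocks, y_blocks = [X.values], [Y.values]
    new_ids = list(X.sample_ids)
    assignments = dict(groups.assignments)
    for r in range(1, rounds):
        x_blocks.append(X.values + rng.normal(0.0, cfg.noise_sd, size=X.values.shape))
        y_blocks.append(Y.values + rng.normal(0.0, cfg.noise_sd, size=Y.values.shape))
        for s in X.sample_ids:
            aug_id = f"{s}__aug{r}"
            new_ids.append(aug_id)
            assignments[aug_id] = groups.assignments[s]

    X_aug = ExpressionMatrix(
        feature_ids=list(X.feature_ids),
        sample_ids=new_ids,
        values=np.concatenate(x_blocks, axis=1),
        scale_tag=X.scale_tag,
    )
    Y_aug = ExpressionMatrix(
        feature_ids=list(Y.feature_ids),
        sample_ids=new_ids,
        values=np.concatenate(y_blocks, axis=1),
        scale_tag=Y.scale_tag,
    )
    return X_aug, Y_aug, SampleGroups(assignments)
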