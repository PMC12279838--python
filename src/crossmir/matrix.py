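"""Core in-memory containers: expression matrices and sample group sheets.

An :class:`ExpressionMatrix` is a features x samples numeric matrix with a
``scale_tag`` recording where in the processing chain it sits:

* ``counts`` — raw non-negative RNA-seq counts,
* ``log_intensity`` — log-scale intensities (microarray) or log-CPM,
* ``compressed`` — globally rescaled to the [0, 1] interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCALE_TAGS = ("counts", "log_intensity", "compressed")
CONDITIONS = ("control", "diseased")


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix.

    Parameters
    ----------
    feature_ids
        Row identifiers (genes, probes, miRNAs). Must be unique.
    sample_ids
        Column identifiers. Must be unique.
    values
        2-D float array of shape ``(len(feature_ids), len(sample_ids))``
        containing only finite values.
    scale_tag
        One of ``counts``, ``log_intensity``, ``compressed``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log_intensity"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- conversions ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: str) -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            scale_tag=scale_tag,
        )

    # -- selection --------------------------------------------------------
    def select_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        """Subset (and reorder) rows by feature ID."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in keep]
        return ExpressionMatrix(
            feature_ids=[self.feature_ids[i] for i in rows],
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            scale_tag=self.scale_tag,
        )

    def select_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        """Subset (and reorder) columns by sample ID."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[j] for j in cols],
            values=self.values[:, cols],
            scale_tag=self.scale_tag,
        )

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            scale_tag=scale_tag or self.scale_tag,
        )


@dataclass
class SampleGroups:
    """Assignment of each sample to a condition (``control`` or ``diseased``)."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.assignments.values() if c not in CONDITIONS})
        if bad:
            raise ValueError(
                f"unknown condition label(s) {bad}; allowed labels are {list(CONDITIONS)}"
            )

    def condition_of(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def samples_in(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {list(CONDITIONS)}")
        return [s for s, c in self.assignments.items() if c == condition]

    def group_sizes(self) -> dict[str, int]:
        return {c: len(self.samples_in(c)) for c in CONDITIONS}

    def subset(self, sample_ids: Iterable[str]) -> "SampleGroups":
        return SampleGroups({s: self.assignments[s] for s in sample_ids})

    def validate_against(self, matrix: ExpressionMatrix, require_two_per_group: bool = False) -> None:
        """Check every matrix sample is assigned exactly once.

        With ``require_two_per_group`` also enforce the two-sample minimum
        each group needs for differential expression.
        """
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        if require_two_per_group:
            sizes = {
                c: sum(1 for s in matrix.sample_ids if self.assignments[s] == c)
                for c in CONDITIONS
            }
            small = {c: n for c, n in sizes.items() if n < 2}
            if small:
                raise ValueError(
                    f"each condition needs >=2 samples for DEA, got {sizes}"
                )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleGroups":
        return cls(dict(mapping))

    def __len__(self) -> int:
        return len(self.assignments)
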