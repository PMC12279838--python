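"""Reading and writing expression matrices, sample sheets and TF lists.

File conventions
----------------
Expression matrix: delimited text, header row = sample IDs, first column =
feature IDs. Sample sheet: two delimited columns ``sample_id, condition``
with condition in {control, diseased}. TF list: plain text, one symbol per
line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CONDITIONS, ExpressionMatrix, SampleGroups

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file."""


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    scale_tag: str = "log_intensity",
) -> ExpressionMatrix:
    """Load a features x samples matrix from a delimited text file.

    Duplicate feature IDs are collapsed by their mean; rows containing any
    non-finite value are dropped. Both events are logged with counts.

    Raises
    ------
    ParseError
        On an empty matrix, malformed header, or a non-numeric cell. The
        error names the offending cell as "row R, column C" where the header
        counts as row 1 and the feature-ID column as column 1.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse header/table: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    if raw.columns.isnull().any() or raw.index.isnull().any():
        raise ParseError(f"{path}: malformed header or feature-ID column")

    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_str = raw.to_numpy(dtype=object)
    # literal NaN/inf tokens and empty cells parse to non-finite and are
    # handled by row dropping below; anything else non-numeric is an error
    nonfinite_tokens = {"", "nan", "na", "inf", "+inf", "-inf", "infinity", "-infinity"}
    is_token = np.frompyfunc(
        lambda s: pd.isnull(s) or str(s).strip().lower() in nonfinite_tokens, 1, 1
    )(raw_str).astype(bool)
    bad = np.isnan(values) & ~is_token
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {raw_str[r, c]!r} at row {r + 2}, "
            f"column {c + 2}"
        )

    df = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))

    n_dup = df.index.duplicated().sum()
    if n_dup:
        logger.info("%s: collapsed %d duplicate feature ID rows by mean", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()

    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_drop = int((~finite).sum())
    if n_drop:
        logger.info("%s: dropped %d rows with non-finite values", path, n_drop)
        df = df.loc[finite]
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no rows left after dropping non-finite rows")

    return ExpressionMatrix.from_frame(df, scale_tag=scale_tag)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="feature_id")


def read_sample_groups(path: str | Path, delimiter: str = "\t") -> SampleGroups:
    """Load a two-column ``sample_id, condition`` sheet.

    Condition labels outside {control, diseased} are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: sample sheet needs columns sample_id, condition")
    sid, cond = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str).str.strip()
    if sid.duplicated().any():
        dups = sorted(sid[sid.duplicated()].unique())
        raise ParseError(f"{path}: duplicate sample IDs in sheet: {dups}")
    bad = sorted(set(cond) - set(CONDITIONS))
    if bad:
        raise ParseError(
            f"{path}: unknown condition label(s) {bad}; allowed labels are "
            f"{list(CONDITIONS)}"
        )
    return SampleGroups(dict(zip(sid, cond)))


def write_sample_groups(groups: SampleGroups, path: str | Path, delimiter: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": list(groups.assignments), "condition": list(groups.assignments.values())}
    ).to_csv(path, sep=delimiter, index=False)


def read_tf_list(path: str | Path) -> set[str]:
    """Plain-text transcription-factor symbols, one per line, case-folded."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            out.add(sym.upper())
    return out


def align_feature_spaces(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared features for cross-study runs.

    Matching is a case-insensitive exact match on feature IDs (no probe-to-
    gene translation). Both outputs carry the case-folded (uppercase) IDs in
    the train matrix's original row order.
    """
    train_fold = [f.upper() for f in train.feature_ids]
    test_fold = [f.upper() for f in test.feature_ids]
    test_set = set(test_fold)
    shared = [f for f in train_fold if f in test_set]
    if not shared:
        raise ValueError(
            "no shared feature IDs between train and test matrices; "
            "harmonize identifiers (e.g. map probes to gene symbols) first"
        )
    logger.info(
        "feature alignment: %d shared of %d train / %d test features",
        len(shared), train.n_features, test.n_features,
    )

    def _subset(m: ExpressionMatrix, folded: list[str]) -> ExpressionMatrix:
        index = {f: i for i, f in enumerate(folded)}
        rows = [index[f] for f in shared]
        return ExpressionMatrix(
            feature_ids=list(shared),
            sample_ids=list(m.sample_ids),
            values=m.values[rows, :],
            scale_tag=m.scale_tag,
        )

    return _subset(train, train_fold), _subset(test, test_fold)
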