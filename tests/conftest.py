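import numpy as np
import pytest

from crossmir import ExpressionMatrix, SampleGroups, SimConfig, simulate_paired_dataset


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2"],
        values=np.array([[5.0, 4.0], [2.0, 1.0], [3.0, 8.0]]),
        scale_tag="log_intensity",
    )


@pytest.fixture
def two_group_sheet() -> SampleGroups:
    return SampleGroups(
        {f"c{i}": "control" for i in range(1, 6)} | {f"d{i}": "diseased" for i in range(1, 6)}
    )


@pytest.fixture
def tiny_sim():
    """A small but non-trivial simulated paired dataset (fast)."""
    cfg = SimConfig(n_mirna=40, n_mrna=150, targets_per_mirna=8, seed=7)
    return cfg, *simulate_paired_dataset(cfg)


def make_matrix(values, scale_tag="log_intensity", prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        feature_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        scale_tag=scale_tag,
    )
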