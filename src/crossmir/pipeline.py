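"""Within-data and cross-study evaluation runs.

A run wires the stages together: optional low-expression filtering ->
global [0, 1] compression -> optional Gaussian augmentation -> model
training (jointly over conditions or one model per condition) -> prediction
on the *original* (non-augmented) samples -> differential expression on the
true and predicted miRNA matrices -> concordance report.

Cross-study runs first intersect the mRNA and miRNA feature spaces of the
two datasets, train on dataset A, re-use A's compression parameters on
dataset B (clipping out-of-range values), and evaluate predictions against
B's true miRNA data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_gaussian
from .dea import run_dea_pair
from .evaluate import ConcordanceReport, build_report
from .io import align_feature_spaces
from .lasso import LassoModelSet, fit_lasso_per_mirna, predict_lasso
from .matrix import CONDITIONS, ExpressionMatrix, SampleGroups
from .mlp import MLPConfig, TrainedPredictor, build_mlp, predict_mlp, train_mlp
from .preprocess import apply_compression, filter_low_expressed, fit_compression

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one evaluation run."""

    model: str = "mlp"                      # "mlp" | "lasso"
    condition_handling: str = "separate"    # "joint" | "separate"
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    filter_fraction: float | None = None    # None/0 disables the expression filter
    compress_per_feature: bool = False
    lambda_choice: str = "minimal"          # lasso only
    nlambda: int = 100
    lambda_ratio: float = 0.01
    mlp: MLPConfig = field(default_factory=MLPConfig)
    allow_lasso_joint: bool = False
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.model not in ("mlp", "lasso"):
            raise ValueError("model must be 'mlp' or 'lasso'")
        if self.condition_handling not in ("joint", "separate"):
            raise ValueError("condition_handling must be 'joint' or 'separate'")
        if self.model == "lasso" and self.condition_handling == "joint" and not self.allow_lasso_joint:
            raise ValueError(
                "LASSO models are fitted per condition; pass allow_lasso_joint=True "
                "to override"
            )
        # propagate the run seed to seeded sub-configs that kept their defaults
        if self.augment is not None and self.augment.seed == 0 and self.seed != 0:
            self.augment = dataclasses.replace(self.augment, seed=self.seed)
        if self.mlp.seed == 0 and self.seed != 0:
            self.mlp = dataclasses.replace(self.mlp, seed=self.seed)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir) if self.outdir else None
        return d


def _train_one(
    X: ExpressionMatrix, Y: ExpressionMatrix, cfg: RunConfig, seed_offset: int = 0
) -> TrainedPredictor:
    if cfg.model == "mlp":
        mlp_cfg = dataclasses.replace(cfg.mlp, seed=cfg.mlp.seed + seed_offset)
        model = build_mlp(X.n_features, Y.n_features, mlp_cfg)
        predictor, history = train_mlp(model, X, Y, mlp_cfg)
        predictor.history = history  # kept for reporting
        return predictor
    models = fit_lasso_per_mirna(X, Y, nlambda=cfg.nlambda, ratio=cfg.lambda_ratio)
    return TrainedPredictor(
        kind="lasso",
        input_feature_ids=list(X.feature_ids),
        output_feature_ids=list(Y.feature_ids),
        state=models,
        lambda_choice=cfg.lambda_choice,
    )


def _predict(predictor: TrainedPredictor, X: ExpressionMatrix, cfg: RunConfig) -> ExpressionMatrix:
    if predictor.kind == "mlp":
        return predict_mlp(predictor, X)
    assert isinstance(predictor.state, LassoModelSet)
    return predict_lasso(predictor.state, X, lambda_choice=cfg.lambda_choice)


def _fit_models(
    X_train: ExpressionMatrix,
    Y_train: ExpressionMatrix,
    groups_train: SampleGroups,
    cfg: RunConfig,
) -> dict[str, TrainedPredictor]:
    """Train one model ("joint") or one per condition ("separate")."""
    if cfg.condition_handling == "joint":
        return {"joint": _train_one(X_train, Y_train, cfg)}
    models = {}
    for offset, cond in enumerate(CONDITIONS):
        ids = [s for s in X_train.sample_ids if groups_train.condition_of(s) == cond]
        if not ids:
            raise ValueError(f"no samples in condition {cond!r} for separate training")
        models[cond] = _train_one(
            X_train.select_samples(ids), Y_train.select_samples(ids), cfg, seed_offset=offset
        )
    return models


def _predict_by_condition(
    models: dict[str, TrainedPredictor],
    X: ExpressionMatrix,
    groups: SampleGroups,
    cfg: RunConfig,
) -> ExpressionMatrix:
    """Predict each sample with its condition-matched model, keeping order."""
    if "joint" in models:
        return _predict(models["joint"], X, cfg)
    columns: dict[str, np.ndarray] = {}
    feature_ids = None
    for cond, predictor in models.items():
        ids = [s for s in X.sample_ids if groups.condition_of(s) == cond]
        if not ids:
            continue
        pred = _predict(predictor, X.select_samples(ids), cfg)
        feature_ids = pred.feature_ids
        for j, s in enumerate(ids):
            columns[s] = pred.values[:, j]
    values = np.column_stack([columns[s] for s in X.sample_ids])
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=list(X.sample_ids),
        values=values,
        scale_tag=X.scale_tag,
    )


def _prepare(
    X: ExpressionMatrix, Y: ExpressionMatrix, cfg: RunConfig, label: str
) -> tuple[ExpressionMatrix, ExpressionMatrix, object, object]:
    """Filter (optionally) and compress a paired dataset with its own params."""
    if cfg.filter_fraction:
        X = filter_low_expressed(X, cfg.filter_fraction)
        Y = filter_low_expressed(Y, cfg.filter_fraction)
    px = fit_compression(X, per_feature=cfg.compress_per_feature, label=f"{label}:mrna")
    py = fit_compression(Y, per_feature=cfg.compress_per_feature, label=f"{label}:mirna")
    Xc, _ = apply_compression(X, px)
    Yc, _ = apply_compression(Y, py)
    return Xc, Yc, px, py


def _write_artifacts(outdir, cfg, report, dea_true, dea_pred) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg.echo(), indent=2, default=str))
    report.to_json(out / "report.json")
    report.per_sample_frame().to_csv(out / "per_sample_r.tsv", sep="\t", index=False)
    dea_true.write_tsv(out / "dea_true.tsv")
    dea_pred.write_tsv(out / "dea_predicted.tsv")
    # scatter data for logFC_true vs logFC_pred plots
    pd.DataFrame(
        {"feature_id": dea_true.feature_ids, "logFC_true": dea_true.logfc,
         "logFC_pred": dea_pred.logfc, "p_true": dea_true.p_raw, "p_pred": dea_pred.p_raw}
    ).to_csv(out / "logfc_scatter.tsv", sep="\t", index=False)


def run_within(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    groups: SampleGroups,
    cfg: RunConfig | None = None,
) -> ConcordanceReport:
    """Train and evaluate on the same dataset (the optimistic bound).

    Models are trained on the (optionally augmented) compressed data and
    evaluated by predicting the *original* samples, so the concordance is
    measured against real profiles only.
    """
    cfg = cfg or RunConfig()
    if X.sample_ids != Y.sample_ids:
        raise ValueError("paired matrices must share samples in order")
    groups.validate_against(X, require_two_per_group=True)

    Xc, Yc, _, _ = _prepare(X, Y, cfg, "train")
    X_orig, Y_orig, groups_orig = Xc, Yc, groups.subset(Xc.sample_ids)

    if cfg.augment is not None:
        X_train, Y_train, groups_train = augment_gaussian(Xc, Yc, groups_orig, cfg.augment)
        logger.info("augmentation: %d -> %d samples", Xc.n_samples, X_train.n_samples)
    else:
        X_train, Y_train, groups_train = Xc, Yc, groups_orig

    models = _fit_models(X_train, Y_train, groups_train, cfg)
    Y_pred = _predict_by_condition(models, X_orig, groups_orig, cfg)
    dea_true, dea_pred = run_dea_pair(Y_orig, Y_pred, groups_orig)
    report = build_report(
        Y_orig, Y_pred, dea_true, dea_pred,
        metadata={
            "mode": "within",
            "model": cfg.model,
            "condition_handling": cfg.condition_handling,
            "augmented": cfg.augment is not None,
            "filter_fraction": cfg.filter_fraction or 0.0,
            "lambda_choice": cfg.lambda_choice if cfg.model == "lasso" else None,
            "seed": cfg.seed,
        },
    )
    if cfg.outdir:
        _write_artifacts(cfg.outdir, cfg, report, dea_true, dea_pred)
    return report


def run_cross_study(
    X_train: ExpressionMatrix,
    Y_train: ExpressionMatrix,
    groups_train: SampleGroups,
    X_test: ExpressionMatrix,
    Y_test: ExpressionMatrix,
    groups_test: SampleGroups,
    cfg: RunConfig | None = None,
) -> ConcordanceReport:
    """Train on study A, predict and evaluate on independent study B.

    Feature spaces are intersected case-insensitively; the training
    compression parameters are re-used on the test matrices (out-of-range
    test values are clipped). With separate condition handling the test
    sample sheet selects which condition's model predicts each test sample.
    """
    cfg = cfg or RunConfig()
    groups_train.validate_against(X_train)
    groups_test.validate_against(X_test, require_two_per_group=True)

    X_train, X_test = align_feature_spaces(X_train, X_test)
    Y_train, Y_test = align_feature_spaces(Y_train, Y_test)

    if cfg.filter_fraction:
        X_train = filter_low_expressed(X_train, cfg.filter_fraction)
        Y_train = filter_low_expressed(Y_train, cfg.filter_fraction)
        X_test = X_test.select_features(X_train.feature_ids)
        Y_test = Y_test.select_features(Y_train.feature_ids)

    px = fit_compression(X_train, per_feature=cfg.compress_per_feature, label="train:mrna")
    py = fit_compression(Y_train, per_feature=cfg.compress_per_feature, label="train:mirna")
    Xc_train, _ = apply_compression(X_train, px)
    Yc_train, _ = apply_compression(Y_train, py)
    Xc_test, nx = apply_compression(X_test, px)
    Yc_test, ny = apply_compression(Y_test, py)
    if nx or ny:
        logger.info("cross-study compression clipped %d mRNA / %d miRNA entries", nx, ny)

    gtr = groups_train.subset(Xc_train.sample_ids)
    if cfg.augment is not None:
        Xa, Ya, ga = augment_gaussian(Xc_train, Yc_train, gtr, cfg.augment)
    else:
        Xa, Ya, ga = Xc_train, Yc_train, gtr

    models = _fit_models(Xa, Ya, ga, cfg)
    gte = groups_test.subset(Xc_test.sample_ids)
    Y_pred = _predict_by_condition(models, Xc_test, gte, cfg)
    dea_true, dea_pred = run_dea_pair(Yc_test, Y_pred, gte)
    report = build_report(
        Yc_test, Y_pred, dea_true, dea_pred,
        metadata={
            "mode": "cross_study",
            "model": cfg.model,
            "condition_handling": cfg.condition_handling,
            "augmented": cfg.augment is not None,
            "n_shared_mrna": X_train.n_features,
            "n_shared_mirna": Y_train.n_features,
            "clipped_test_entries": int(nx + ny),
            "seed": cfg.seed,
        },
    )
    if cfg.outdir:
        _write_artifacts(cfg.outdir, cfg, report, dea_true, dea_pred)
    return report


def compare_settings(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    groups: SampleGroups,
    base_cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Within-data grid over augmentation x condition handling.

    Returns one row per setting with the concordance metrics and the change
    in r_logfc relative to the no-augmentation / joint baseline.
    """
    base_cfg = base_cfg or RunConfig()
    rows = []
    for augmented in (False, True):
        for handling in ("joint", "separate"):
            cfg = dataclasses.replace(
                base_cfg,
                augment=(base_cfg.augment or AugmentConfig(seed=base_cfg.seed)) if augmented else None,
                condition_handling=handling,
                allow_lasso_joint=True,
                outdir=None,
            )
            report = run_within(X, Y, groups, cfg)
            rows.append(
                {
                    "augmented": augmented,
                    "condition_handling": handling,
                    "median_sample_r": report.median_sample_r,
                    "r_logfc": report.r_logfc,
                    "r_pvalue": report.r_pvalue,
                }
            )
    df = pd.DataFrame(rows)
    baseline = df.loc[(~df["augmented"]) & (df["condition_handling"] == "joint"), "r_logfc"].iloc[0]
    df["delta_r_logfc"] = df["r_logfc"] - baseline
    return df
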