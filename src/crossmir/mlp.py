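"""Multi-output feed-forward network mapping mRNA profiles to miRNA profiles.

Architecture: input (one unit per mRNA feature) -> four dense hidden layers
of 1024/512/256/128 units by default, each followed by batch normalization,
ReLU and dropout (rate 0.4), with an L2 penalty on every dense kernel ->
linear output layer with one unit per miRNA. Training minimizes mean squared
error (mean absolute error tracked as the metric) with Adam at learning rate
0.001, a batch size of 32, at most 150 epochs, a 20% validation split, and
a scheduler that halves the learning rate when the validation loss plateaus.

The implementation is self-contained NumPy (forward/backward passes written
out), which makes seeded runs bit-reproducible on a single thread. float32
arithmetic keeps the default architecture trainable on one CPU in seconds
to a few tens of seconds per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

_BN_EPS = 1e-3          # keras BatchNormalization default
_BN_MOMENTUM = 0.99     # running-statistics momentum
_ADAM_EPS = 1e-7


@dataclass
class MLPConfig:
    hidden_sizes: list[int] = field(default_factory=lambda: [1024, 512, 256, 128])
    activation: str = "relu"
    batchnorm_after_dense: bool = True
    l2_coeff: float = 1e-4
    dropout_rate: float = 0.4
    output_activation: str = "linear"
    loss: str = "mse"
    metric: str = "mae"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 5
    min_lr: float = 1e-6
    max_epochs: int = 150
    batch_size: int = 32
    validation_split: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be nonempty and strictly positive")
        for name, allowed in (
            ("activation", "relu"), ("output_activation", "linear"),
            ("loss", "mse"), ("metric", "mae"), ("optimizer", "adam"),
        ):
            if getattr(self, name) != allowed:
                raise ValueError(f"{name} supports only {allowed!r}")


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_mae: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epoch)


class MLPModel:
    """Untrained-to-trained network state. Build with :func:`build_mlp`."""

    def __init__(self, n_in: int, n_out: int, cfg: MLPConfig):
        if n_in < 1 or n_out < 1:
            raise ValueError("n_in and n_out must be >= 1")
        self.n_in = n_in
        self.n_out = n_out
        self.cfg = cfg
        self.trained = False
        rng = np.random.default_rng(cfg.seed)
        widths = [n_in] + list(cfg.hidden_sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        self.gamma: list[np.ndarray] = []
        self.beta: list[np.ndarray] = []
        self.run_mean: list[np.ndarray] = []
        self.run_var: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # He initialization for ReLU layers
            self.W.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)
            )
            self.b.append(np.zeros(fan_out, dtype=np.float32))
            self.gamma.append(np.ones(fan_out, dtype=np.float32))
            self.beta.append(np.zeros(fan_out, dtype=np.float32))
            self.run_mean.append(np.zeros(fan_out, dtype=np.float32))
            self.run_var.append(np.ones(fan_out, dtype=np.float32))
        # Glorot for the linear output layer
        limit = np.sqrt(6.0 / (widths[-1] + n_out))
        self.W_out = rng.uniform(-limit, limit, size=(widths[-1], n_out)).astype(np.float32)
        self.b_out = np.zeros(n_out, dtype=np.float32)

    # -- introspection ------------------------------------------------------
    @property
    def layer_widths(self) -> list[int]:
        """Widths of the hidden layers followed by the output width."""
        return [w.shape[1] for w in self.W] + [self.n_out]

    @property
    def first_layer_weights(self) -> np.ndarray:
        """Kernel of the first dense layer, shape (n_in, first hidden width)."""
        return np.asarray(self.W[0], dtype=float)

    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, *self.gamma, *self.beta, self.W_out, self.b_out]

    # -- forward ------------------------------------------------------------
    def _forward_train(self, x: np.ndarray, rng: np.random.Generator):
        cache = []
        a = x
        keep = 1.0 - self.cfg.dropout_rate
        for l in range(len(self.W)):
            z = a @ self.W[l] + self.b[l]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv
            bn = self.gamma[l] * zhat + self.beta[l]
            self.run_mean[l] = (_BN_MOMENTUM * self.run_mean[l] + (1 - _BN_MOMENTUM) * mu).astype(np.float32)
            self.run_var[l] = (_BN_MOMENTUM * self.run_var[l] + (1 - _BN_MOMENTUM) * var).astype(np.float32)
            relu_mask = bn > 0
            h = bn * relu_mask
            if self.cfg.dropout_rate > 0:
                drop_mask = (rng.random(h.shape) < keep).astype(np.float32) / keep
                h = h * drop_mask
            else:
                drop_mask = None
            cache.append((a, z, mu, inv, zhat, relu_mask, drop_mask))
            a = h
        yhat = a @ self.W_out + self.b_out
        return yhat, a, cache

    def forward_inference(self, x: np.ndarray) -> np.ndarray:
        a = x.astype(np.float32)
        for l in range(len(self.W)):
            z = a @ self.W[l] + self.b[l]
            inv = 1.0 / np.sqrt(self.run_var[l] + _BN_EPS)
            bn = self.gamma[l] * (z - self.run_mean[l]) * inv + self.beta[l]
            a = np.maximum(bn, 0.0)
        return a @ self.W_out + self.b_out

    # -- backward -----------------------------------------------------------
    def _backward(self, x, y, rng):
        """One forward/backward pass; returns (grads, mse, mae)."""
        yhat, a_last, cache = self._forward_train(x, rng)
        B = x.shape[0]
        err = yhat - y
        mse = float(np.mean(err ** 2))
        mae = float(np.mean(np.abs(err)))
        dyhat = (2.0 / err.size) * err

        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        gg = [None] * len(self.W)
        gbeta = [None] * len(self.W)
        gW_out = a_last.T @ dyhat + 2 * self.cfg.l2_coeff * self.W_out
        gb_out = dyhat.sum(axis=0)
        da = dyhat @ self.W_out.T
        for l in range(len(self.W) - 1, -1, -1):
            a_prev, z, mu, inv, zhat, relu_mask, drop_mask = cache[l]
            dh = da
            if drop_mask is not None:
                dh = dh * drop_mask
            dbn = dh * relu_mask
            gg[l] = (dbn * zhat).sum(axis=0)
            gbeta[l] = dbn.sum(axis=0)
            dzhat = dbn * self.gamma[l]
            # batchnorm backward (batch statistics)
            dz = (
                dzhat
                - dzhat.mean(axis=0)
                - zhat * (dzhat * zhat).mean(axis=0)
            ) * inv
            gW[l] = a_prev.T @ dz + 2 * self.cfg.l2_coeff * self.W[l]
            gb[l] = dz.sum(axis=0)
            da = dz @ self.W[l].T
        grads = [*gW, *gb, *gg, *gbeta, gW_out, gb_out]
        return grads, mse, mae


def build_mlp(n_in: int, n_out: int, cfg: MLPConfig | None = None) -> MLPModel:
    """Construct the (untrained) network for given input/output widths."""
    return MLPModel(n_in, n_out, cfg or MLPConfig())


@dataclass
class TrainedPredictor:
    """A fitted mRNA -> miRNA mapping (MLP or LASSO set)."""

    kind: str  # "mlp" | "lasso"
    input_feature_ids: list[str]
    output_feature_ids: list[str]
    state: object  # MLPModel or LassoModelSet
    lambda_choice: str | None = None

    @property
    def first_layer_weights(self) -> np.ndarray:
        if self.kind != "mlp":
            raise ValueError("first-layer weights exist only for MLP predictors")
        return self.state.first_layer_weights


class _Adam:
    def __init__(self, params: list[np.ndarray]):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.beta1, self.beta2 = 0.9, 0.999

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= (lr * (m / b1c) / (np.sqrt(v / b2c) + _ADAM_EPS)).astype(p.dtype)


def train_mlp(
    model: MLPModel,
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    cfg: MLPConfig | None = None,
) -> tuple[TrainedPredictor, TrainingHistory]:
    """Train the network on compressed mRNA (X) and miRNA (Y) matrices.

    Samples become training rows. The (seeded) shuffled sample order's last
    ``validation_split`` fraction forms the validation set; the learning
    rate is halved after ``lr_plateau_patience`` epochs without validation
    improvement, with a floor at ``min_lr``. Same seed + same data =>
    identical training trajectory (single-threaded determinism).
    """
    cfg = cfg or model.cfg
    if X.sample_ids != Y.sample_ids:
        raise ValueError("X and Y must share sample IDs and order")
    if X.n_features != model.n_in or Y.n_features != model.n_out:
        raise ValueError(
            f"matrix dimensions ({X.n_features} -> {Y.n_features}) do not match "
            f"the network ({model.n_in} -> {model.n_out})"
        )
    n = X.n_samples
    n_val = int(np.floor(cfg.validation_split * n))
    if n_val < 1:
        raise ValueError(
            f"{n} samples leave an empty {cfg.validation_split:.0%} validation "
            "split; augment the training data first"
        )

    rng = np.random.default_rng([cfg.seed, 2])
    order = rng.permutation(n)
    train_idx, val_idx = order[: n - n_val], order[n - n_val:]
    Xall = np.ascontiguousarray(X.values.T, dtype=np.float32)
    Yall = np.ascontiguousarray(Y.values.T, dtype=np.float32)
    Xtr, Ytr = Xall[train_idx], Yall[train_idx]
    Xva, Yva = Xall[val_idx], Yall[val_idx]

    params = model.parameters()
    opt = _Adam(params)
    lr = cfg.learning_rate
    best_val = np.inf
    wait = 0
    history = TrainingHistory()
    n_tr = Xtr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n_tr)
        losses, maes = [], []
        for start in range(0, n_tr, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch statistics need >=2 rows
            grads, mse, mae = model._backward(Xtr[idx], Ytr[idx], rng)
            opt.step(params, grads, lr)
            losses.append(mse)
            maes.append(mae)
        val_pred = model.forward_inference(Xva)
        val_loss = float(np.mean((val_pred - Yva) ** 2))
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_mae.append(float(np.mean(maes)))
        history.val_loss.append(val_loss)
        history.learning_rate.append(lr)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            wait = 0
        else:
            wait += 1
            if wait >= cfg.lr_plateau_patience:
                lr = max(lr * cfg.lr_plateau_factor, cfg.min_lr)
                wait = 0

    # final batch-norm calibration: replace the exponentially smoothed running
    # statistics with the exact activation statistics of the full training
    # data, so inference mode matches the distribution the weights were
    # trained against (the smoothed estimates lag badly after few steps)
    a = Xtr
    for l in range(len(model.W)):
        z = a @ model.W[l] + model.b[l]
        model.run_mean[l] = z.mean(axis=0).astype(np.float32)
        model.run_var[l] = z.var(axis=0).astype(np.float32)
        bn = model.gamma[l] * (z - model.run_mean[l]) / np.sqrt(
            model.run_var[l] + _BN_EPS
        ) + model.beta[l]
        a = np.maximum(bn, 0.0).astype(np.float32)

    model.trained = True
    predictor = TrainedPredictor(
        kind="mlp",
        input_feature_ids=list(X.feature_ids),
        output_feature_ids=list(Y.feature_ids),
        state=model,
    )
    return predictor, history


def predict_mlp(predictor: TrainedPredictor, X: ExpressionMatrix) -> ExpressionMatrix:
    """Predict the miRNA matrix for new mRNA samples (inference mode).

    Dropout is disabled and batch normalization uses the running statistics,
    so prediction is deterministic and per-sample independent.
    """
    if predictor.kind != "mlp":
        raise ValueError("predictor is not an MLP")
    if X.feature_ids != predictor.input_feature_ids:
        raise ValueError("input features do not match the trained model (IDs and order)")
    model: MLPModel = predictor.state
    yhat = model.forward_inference(np.ascontiguousarray(X.values.T, dtype=np.float32))
    return ExpressionMatrix(
        feature_ids=list(predictor.output_feature_ids),
        sample_ids=list(X.sample_ids),
        values=yhat.T.astype(float),
        scale_tag=X.scale_tag,
    )
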