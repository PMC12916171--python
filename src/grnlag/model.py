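"""The hybrid recurrent-convolutional pair classifier.

Each candidate TF->target pair is represented by its (enhanced) p x q delay
correlation matrix.  The matrix is read as a length-p sequence of
q-dimensional steps — TF windows advance along pseudotime, so rows are the
natural recurrent axis — and passed through a bidirectional GRU returning
the full sequence.  The (p, 2*units) output is treated as a single-channel
2-D map from which a small convolutional stack extracts local patterns,
followed by max pooling, dropout, and three dense layers (512, 128, 1) with
a sigmoid output giving the interaction probability.

Ablation variants swap the recurrent backbone (GRU, LSTM, SimpleRNN, none =
CNN-only) or change the convolutional depth (including no convolutions =
BiGRU-only).  Training minimizes binary cross-entropy with SGD (momentum,
exponentially decaying learning rate) and keeps the parameters of the epoch
with the best validation AUPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nn

__all__ = [
    "ModelConfig", "TrainedModel", "FeaturizedPair",
    "build_model", "train", "predict", "save_model", "load_model",
]

logger = logging.getLogger(__name__)

_BACKBONES = ("bigru", "gru", "lstm", "simple_rnn", "none")


@dataclass(frozen=True)
class FeaturizedPair:
    """A directed candidate pair with its feature matrix and binary label."""

    tf_id: str
    target_id: str
    label: int
    matrix: np.ndarray


@dataclass
class ModelConfig:
    gru_units: int = 128
    backbone: str = "bigru"
    conv_filters: list[int] = field(default_factory=lambda: [64, 32])
    kernel_size: int = 3
    pool_size: int = 2
    dropout_conv: float = 0.25
    dropout_dense: float = 0.5
    dense_sizes: list[int] = field(default_factory=lambda: [512, 128, 1])
    lr: float = 0.01
    lr_decay: float = 0.95
    momentum: float = 0.9
    epochs: int = 60
    batch_size: int = 32
    patience: int = 10
    seed: int = 0
    dtype: str = "float32"
    transpose_input: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(f"backbone must be one of {_BACKBONES}")
        if self.dense_sizes[-1] != 1:
            raise ValueError("final dense layer must have size 1 (binary output)")
        if not 0 <= len(self.conv_filters) <= 4:
            raise ValueError("conv_filters supports 0 to 4 layers")
        for r in (self.dropout_conv, self.dropout_dense):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")


@dataclass
class TrainedModel:
    config: ModelConfig
    input_shape: tuple[int, int]
    network: nn.Network
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.network.params())


def build_model(cfg: ModelConfig, input_shape: tuple[int, int]) -> TrainedModel:
    """Construct the (untrained) network for p x q input matrices."""
    p, q = input_shape
    if cfg.transpose_input:
        p, q = q, p
    dtype = np.dtype(cfg.dtype).type
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

    layers: list[nn.Layer] = []
    if cfg.transpose_input:
        layers.append(_Transpose())
    if cfg.backbone == "bigru":
        layers.append(nn.Bidirectional(nn.GRU, q, cfg.gru_units, rng, dtype=dtype))
        feat = 2 * cfg.gru_units
    elif cfg.backbone == "gru":
        layers.append(nn.GRU(q, cfg.gru_units, rng, dtype=dtype))
        feat = cfg.gru_units
    elif cfg.backbone == "lstm":
        layers.append(nn.LSTM(q, cfg.gru_units, rng, dtype=dtype))
        feat = cfg.gru_units
    elif cfg.backbone == "simple_rnn":
        layers.append(nn.SimpleRNN(q, cfg.gru_units, rng, dtype=dtype))
        feat = cfg.gru_units
    else:  # CNN-only: the raw matrix is the 2-D map
        feat = q

    h, w = p, feat
    if cfg.conv_filters:
        if h < 4 or w < 4:
            raise ValueError(f"map {h}x{w} too small for the convolutional stack")
        layers.append(nn.AddChannel())
        c_in = 1
        for li, filters in enumerate(cfg.conv_filters):
            if h < cfg.kernel_size or w < cfg.kernel_size:
                raise ValueError(
                    f"conv layer {li + 1}: map {h}x{w} smaller than kernel {cfg.kernel_size}"
                )
            layers.append(nn.Conv2D(c_in, filters, cfg.kernel_size, rng, dtype=dtype))
            layers.append(nn.ReLU())
            c_in = filters
            h, w = h - cfg.kernel_size + 1, w - cfg.kernel_size + 1
        if h < cfg.pool_size or w < cfg.pool_size:
            raise ValueError(f"max-pool: map {h}x{w} smaller than pool {cfg.pool_size}")
        layers.append(nn.MaxPool2D(cfg.pool_size))
        h, w = h // cfg.pool_size, w // cfg.pool_size
        layers.append(nn.Dropout(cfg.dropout_conv, drop_rng))
        flat = c_in * h * w
    else:
        flat = h * w
    layers.append(nn.Flatten())

    d_in = flat
    hidden = cfg.dense_sizes[:-1]
    for d_out in hidden:
        layers.append(nn.Dense(d_in, d_out, rng, dtype=dtype))
        layers.append(nn.ReLU())
        d_in = d_out
    layers.append(nn.Dropout(cfg.dropout_dense, drop_rng))
    layers.append(nn.Dense(d_in, 1, rng, dtype=dtype))  # logit; sigmoid applied at loss/predict

    model = TrainedModel(config=cfg, input_shape=input_shape, network=nn.Network(layers))
    logger.info(
        "built %s model for %sx%s input: %d parameters",
        cfg.backbone, *input_shape, model.n_params,
    )
    return model


class _Transpose(nn.Layer):
    def forward(self, x, train=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dout):
        return np.ascontiguousarray(dout.transpose(0, 2, 1))


def _stack(pairs: list[FeaturizedPair], shape: tuple[int, int], dtype) -> tuple[np.ndarray, np.ndarray]:
    for pr in pairs:
        if pr.matrix.shape != shape:
            raise ValueError(
                f"pair ({pr.tf_id}, {pr.target_id}) matrix {pr.matrix.shape} does not "
                f"match expected input shape {shape}"
            )
    X = np.stack([pr.matrix for pr in pairs]).astype(dtype)
    y = np.array([pr.label for pr in pairs], dtype=np.float64)
    return X, y


def train(
    model: TrainedModel,
    train_pairs: list[FeaturizedPair],
    val_pairs: list[FeaturizedPair],
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Fit with minibatch SGD; keep the epoch with the best validation AUPR."""
    cfg = cfg or model.config
    dtype = np.dtype(cfg.dtype).type
    X_tr, y_tr = _stack(train_pairs, model.input_shape, dtype)
    X_va, y_va = _stack(val_pairs, model.input_shape, dtype)
    for name, y in (("training", y_tr), ("validation", y_va)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set contains a single class; cannot fit or select")

    net = model.network
    opt = nn.SGD(net.params(), lr=cfg.lr, momentum=cfg.momentum, decay=cfg.lr_decay)
    batch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    best_aupr = -np.inf
    best_loss = np.inf
    best_state = net.get_state()
    best_epoch = 0
    stale = 0
    for epoch in range(cfg.epochs):
        opt.set_epoch(epoch)
        order = batch_rng.permutation(len(X_tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(X_tr[idx], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged (epoch {epoch + 1}); try a lower learning rate"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_scores = _forward_scores(model, X_va)
        val_auroc = float(roc_auc_score(y_va, val_scores))
        val_aupr = float(average_precision_score(y_va, val_scores))
        model.history.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)),
             "val_auroc": val_auroc, "val_aupr": val_aupr, "lr": opt.lr}
        )
        val_loss, _ = nn.bce_with_logits(
            np.log(np.clip(val_scores, 1e-12, 1 - 1e-12) / np.clip(1 - val_scores, 1e-12, 1)), y_va
        )
        # ties in val AUPR (common with small validation sets) break by val loss
        improved = val_aupr > best_aupr
        if improved or (val_aupr == best_aupr and val_loss < best_loss):
            best_aupr, best_loss, best_epoch = val_aupr, val_loss, epoch + 1
            best_state = net.get_state()
        stale = 0 if improved else stale + 1
        if stale >= cfg.patience:
            logger.info("early stop at epoch %d (best epoch %d)", epoch + 1, best_epoch)
            break
    net.set_state(best_state)
    model.best_epoch = best_epoch
    return model


def _forward_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    scores = np.empty(len(X))
    bs = model.config.batch_size
    for start in range(0, len(X), bs):
        logits = model.network.forward(X[start : start + bs], train=False)
        scores[start : start + bs] = nn.sigmoid(logits.astype(np.float64)).reshape(-1)
    return scores


def predict(model: TrainedModel, matrices: list[np.ndarray]) -> list[float]:
    """Interaction probability in [0, 1] per matrix, order-preserving."""
    shape = model.input_shape
    arrays = [getattr(m, "values", m) for m in matrices]  # EnhancedMatrix or ndarray
    for i, m in enumerate(arrays):
        if m.shape != shape:
            raise ValueError(f"matrix {i} has shape {m.shape}, expected {shape}")
    X = np.stack(arrays).astype(np.dtype(model.config.dtype).type)
    return [float(s) for s in _forward_scores(model, X)]


def save_model(model: TrainedModel, path: str) -> None:
    """Single-archive checkpoint: config + input shape + weights + history."""
    import dataclasses
    import json

    meta = {
        "config": dataclasses.asdict(model.config),
        "input_shape": list(model.input_shape),
        "history": model.history,
        "best_epoch": model.best_epoch,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.network.params())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> TrainedModel:
    import json

    with np.load(path) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        model = build_model(ModelConfig(**meta["config"]), tuple(meta["input_shape"]))
        model.history = meta["history"]
        model.best_epoch = meta["best_epoch"]
        params = model.network.params()
        for i, p in enumerate(params):
            p.value[...] = archive[f"param_{i}"]
    return model
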