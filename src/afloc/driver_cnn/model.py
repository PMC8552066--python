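"""Model construction, training loop and inference for the driver CNN."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .layers import Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2, ReLU, Sequential, Softmax


@dataclasses.dataclass
class CnnSpec:
    input_shape: Tuple[int, int, int]
    conv_filters: Tuple[int, ...] = (32, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: Tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.6
    n_classes: int = 8


@dataclasses.dataclass
class TrainConfig:
    max_epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int = 50
    lr_factor: float = 0.5
    lr_patience: int = 20
    monitor: str = "train_loss"   # or "val_loss"
    rng_seed: int = 0
    min_lr: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be below max_epochs")


@dataclasses.dataclass
class TrainedModel:
    model: Sequential
    spec: CnnSpec
    config: TrainConfig
    history: dict
    best_epoch: int

    @property
    def best_monitor_value(self) -> float:
        return self.history[self.config.monitor][self.best_epoch]


def _validate_shape(spec: CnnSpec) -> Tuple[int, int]:
    h, w, _ = spec.input_shape
    for _ in spec.conv_filters:
        h, w = h - spec.kernel_size + 1, w - spec.kernel_size + 1
        if h < 1 or w < 1:
            raise ValueError(
                f"input shape {spec.input_shape} collapses in the conv stack; "
                "spatial dimensions of at least 30x30 are required"
            )
        h, w = h // spec.pool_size, w // spec.pool_size
        if h < 1 or w < 1:
            raise ValueError(
                f"input shape {spec.input_shape} collapses in the pooling stack; "
                "spatial dimensions of at least 30x30 are required"
            )
    return h, w


def build_custom_cnn(
    input_shape: Tuple[int, int, int],
    n_classes: int = 8,
    spec_overrides: Optional[dict] = None,
    rng_seed: int = 0,
) -> Tuple[CnnSpec, Sequential]:
    """Build the (32, 64, 64)-filter conv stack + (128, 64) dense head."""
    spec = CnnSpec(input_shape=tuple(input_shape), n_classes=n_classes, **(spec_overrides or {}))
    h, w = _validate_shape(spec)
    rng = np.random.default_rng(rng_seed)
    layers = []
    in_ch = spec.input_shape[2]
    for f in spec.conv_filters:
        layers += [Conv2D(in_ch, f, spec.kernel_size, rng=rng), ReLU(), MaxPool2()]
        in_ch = f
    layers.append(Flatten())
    in_features = h * w * in_ch
    # one dropout between the hidden dense layers; a second one before the
    # softmax head degrades convergence badly without helping generalization
    for i, units in enumerate(spec.dense_units):
        layers += [Dense(in_features, units, rng=rng), ReLU()]
        if i < len(spec.dense_units) - 1:
            layers.append(Dropout(spec.dropout_rate, rng=rng))
        in_features = units
    layers += [Dense(in_features, spec.n_classes, rng=rng), Softmax()]
    model = Sequential(layers)
    model.input_shape = spec.input_shape
    return spec, model


def weighted_cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    sample_weights: Optional[np.ndarray] = None,
    reduction: str = "mean",
    eps: float = 1e-12,
) -> float:
    """Categorical cross-entropy with per-sample weights."""
    p = np.clip(probs[np.arange(len(labels)), labels], eps, 1.0)
    ce = -np.log(p)
    if sample_weights is not None:
        ce = ce * sample_weights
    if reduction == "sum":
        return float(ce.sum())
    if reduction == "mean":
        return float(ce.mean())
    raise ValueError("reduction must be 'mean' or 'sum'")


def _epoch_loss(model, x, y, weights, batch_size):
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        probs = model.forward(x[i:i + batch_size], train=False)
        w = None if weights is None else weights[y[i:i + batch_size]]
        total += weighted_cross_entropy(probs, y[i:i + batch_size], w, reduction="sum")
        n += len(probs)
    return total / max(n, 1)


def train_model(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    config: Optional[TrainConfig] = None,
    class_weight: Optional[np.ndarray] = None,
    spec: Optional[CnnSpec] = None,
    alt_images: Optional[np.ndarray] = None,
    alt_every: int = 4,
    verbose: bool = False,
) -> TrainedModel:
    """Class-weighted training with LR reduction, early stopping and
    best-model checkpointing on the monitored metric.

    ``alt_images`` (same labels/order as ``x_train``) enables input
    augmentation: every ``alt_every``-th epoch trains on the alternate
    tensors — e.g. a differently-noised or clean rendering of the same
    frames, which discourages the network from keying on one noise texture.
    """
    config = config or TrainConfig()
    y_train = np.asarray(y_train)
    if len(x_train) == 0 or (config.monitor == "val_loss" and (x_val is None or len(x_val) == 0)):
        raise ValueError("train (and monitored val) splits must be non-empty")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels must cover at least 2 classes")

    rng = np.random.default_rng(config.rng_seed)
    # dropout layers draw from the same seeded stream
    for layer in model.layers:
        if isinstance(layer, Dropout):
            layer.rng = rng

    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "lr": []}
    best_value = np.inf
    best_epoch = -1
    best_params: List[np.ndarray] = []
    epochs_since_best = 0
    epochs_since_lr = 0

    if alt_images is not None and len(alt_images) != len(x_train):
        raise ValueError("alt_images must align with x_train")

    n = len(x_train)
    for epoch in range(config.max_epochs):
        use_alt = alt_images is not None and epoch % alt_every == alt_every - 1
        x_epoch = alt_images if use_alt else x_train
        perm = rng.permutation(n)
        run_loss, run_hits, run_count = 0.0, 0, 0
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb, yb = x_epoch[idx], y_train[idx]
            logits = model.forward_logits(xb, train=True)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
            w = np.ones(len(yb)) if class_weight is None else class_weight[yb]
            if not np.all(np.isfinite(probs)):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            dlogits = ((probs - onehot) * w[:, None] / len(yb)).astype(np.float32)
            model.backward_from_logits(dlogits)
            opt.step(model.gradients())
            run_loss += weighted_cross_entropy(probs, yb, w, reduction="sum")
            run_hits += int((probs.argmax(axis=1) == yb).sum())
            run_count += len(yb)

        train_loss = run_loss / run_count
        if not np.isfinite(train_loss):
            raise RuntimeError(f"NaN loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["train_acc"].append(run_hits / run_count)
        if x_val is not None and len(x_val):
            vw = None if class_weight is None else class_weight
            val_loss = _epoch_loss(model, x_val, np.asarray(y_val), vw, 256)
        else:
            val_loss = np.nan
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        monitored = train_loss if config.monitor == "train_loss" else val_loss
        if use_alt and config.monitor == "train_loss":
            # loss on the alternate tensors is not comparable with the
            # primary epochs; keep checkpoint/patience bookkeeping untouched
            monitored = None
        if verbose:
            print(
                f"epoch {epoch}: train_loss={train_loss:.4f} acc={history['train_acc'][-1]:.3f} "
                f"val_loss={val_loss:.4f} lr={opt.lr:.2e}"
            )

        if monitored is None:
            pass
        elif monitored < best_value - 1e-12:
            best_value = monitored
            best_epoch = epoch
            best_params = [p.copy() for p in model.parameters()]
            epochs_since_best = 0
            epochs_since_lr = 0
        else:
            epochs_since_best += 1
            epochs_since_lr += 1
        if epochs_since_lr > config.lr_patience and opt.lr > config.min_lr:
            opt.lr = max(opt.lr * config.lr_factor, config.min_lr)
            epochs_since_lr = 0
        if epochs_since_best > config.early_stop_patience:
            break

    if best_params:
        model.set_parameters(best_params)
    return TrainedModel(model=model, spec=spec, config=config, history=history, best_epoch=best_epoch)


def predict(model: Sequential, tensors: np.ndarray, batch_size: int = 256):
    """Probabilities and argmax labels; dropout inactive, deterministic."""
    x = np.asarray(tensors, dtype=np.float32)
    expected = getattr(model, "input_shape", None)
    if expected is not None and tuple(x.shape[1:]) != tuple(expected):
        raise ValueError(f"tensor shape {x.shape[1:]} does not match model input {expected}")
    if len(x) == 0:
        return np.zeros((0, model.layers[-2].w.shape[1])), np.zeros(0, dtype=np.int64)
    probs = np.concatenate(
        [model.forward(x[i:i + batch_size], train=False) for i in range(0, len(x), batch_size)]
    )
    return probs, probs.argmax(axis=1).astype(np.int64)


def save_model(trained: TrainedModel, path) -> None:
    """Weights to .npz plus a JSON sidecar (spec, config, history)."""
    path = Path(path)
    if trained.spec is None:
        raise ValueError("cannot persist a model trained without a CnnSpec")
    arrays = {f"p{i}": p for i, p in enumerate(trained.model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "spec": dataclasses.asdict(trained.spec) if trained.spec else None,
        "config": dataclasses.asdict(trained.config),
        "history": {k: [float(v) for v in vals] for k, vals in trained.history.items()},
        "best_epoch": trained.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = CnnSpec(**{**sidecar["spec"], "input_shape": tuple(sidecar["spec"]["input_shape"]),
                      "conv_filters": tuple(sidecar["spec"]["conv_filters"]),
                      "dense_units": tuple(sidecar["spec"]["dense_units"])})
    _, model = build_custom_cnn(spec.input_shape, spec.n_classes)
    data = np.load(path.with_suffix(".npz"))
    model.set_parameters([data[f"p{i}"] for i in range(len(data.files))])
    config = TrainConfig(**sidecar["config"])
    return TrainedModel(model=model, spec=spec, config=config,
                        history=sidecar["history"], best_epoch=sidecar["best_epoch"])
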