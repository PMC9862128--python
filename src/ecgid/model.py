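"""The GAF identification network: a tuned VGG-style convolutional classifier.

Architecture (fixed layer sequence, sizes configurable):

    stem:   [conv(s1) relu, conv(s1) relu, maxpool, conv(s2) relu, conv(s2) relu, maxpool]
    core:   core_conv_layers x [conv(core_filters, 3x3) relu]
    neck:   maxpool, global-average-pool, dropout(dropout_core)
    head:   dense(dense_units) relu, dropout(dropout_head), dense(num_classes) -> softmax

The stem mirrors the first two conv-conv-pool blocks of VGG19; the core is
the tuned block of five 3x3 convolutions.  Two built-in profiles are
provided: ``full`` (VGG19-sized: 64/128 stem, five conv-512 core, Adam at
1e-5) and ``desk`` (the same shape shrunk to train end-to-end in CPU
minutes: 8/16 stem, five conv-32 core, Adam at 1e-3).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import GAFDataset
from .nn import (
    Adam,
    Conv2d,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2,
    Network,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "TrainedModel",
    "desk_config",
    "full_config",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture plus training hyperparameters."""

    num_classes: int
    input_size: int = 64
    channel_mode: str = "single"  # "single" | "replicate3"
    use_pretrained_stem: bool = False
    stem_filters: tuple[int, int] = (8, 16)
    core_conv_layers: int = 5
    core_filters: int = 32
    core_kernel: int = 3
    dropout_core: float = 0.25
    dropout_head: float = 0.10
    dense_units: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5  # multiplied in when validation loss plateaus
    lr_decay_patience: int = 0  # plateau epochs before each decay (0 disables)
    standardize_inputs: bool = False  # per-pixel z-scoring on train-set statistics
    augment_time_shift: bool = False  # random circular window shift while training
    batch_size: int = 16
    max_epochs: int = 40
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if not (0.0 <= self.dropout_core < 1.0 and 0.0 <= self.dropout_head < 1.0):
            raise ConfigurationError("dropout fractions must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer: {self.optimizer!r}")
        if self.core_kernel != 3:
            raise ConfigurationError("only 3x3 kernels are supported")
        if self.channel_mode not in ("single", "replicate3"):
            raise ConfigurationError(f"unknown channel_mode: {self.channel_mode!r}")
        # three 2x2 pools: input must reduce cleanly and not collapse below 2
        if self.input_size % 8 != 0 or self.input_size // 8 < 2:
            raise ConfigurationError(
                f"input_size {self.input_size} too small for the pooling cascade "
                "(need a multiple of 8, at least 16)"
            )


def desk_config(num_classes: int, **overrides) -> ModelConfig:
    """Desk-scale profile: the full architecture's shape at CPU-minutes cost.

    Sized for small cohorts (tens of windows per subject): thin filter
    banks, no dropout (the circular time-shift augmentation regularises
    instead), per-pixel input standardisation, and best-epoch checkpointing
    over a fixed 60-epoch budget (patience equals the budget, so training
    is never arrested on a noisy small-validation loss).
    """
    defaults = dict(
        stem_filters=(8, 16),
        core_filters=64,
        dense_units=128,
        dropout_core=0.0,
        dropout_head=0.0,
        standardize_inputs=True,
        augment_time_shift=True,
        batch_size=8,
        max_epochs=60,
        early_stop_patience=60,
    )
    defaults.update(overrides)
    return ModelConfig(num_classes=num_classes, **defaults)


def full_config(num_classes: int, **overrides) -> ModelConfig:
    """VGG19-sized profile (64/128 stem, five conv-512 core, Adam 1e-5)."""
    defaults = dict(
        input_size=128,
        stem_filters=(64, 128),
        core_filters=512,
        dense_units=256,
        learning_rate=1e-5,
        channel_mode="replicate3",
    )
    defaults.update(overrides)
    return ModelConfig(num_classes=num_classes, **defaults)


@dataclass
class TrainingHistory:
    """Per-epoch curves plus the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


@dataclass
class TrainedModel:
    """A network together with its config and enrolled class order.

    ``feature_mean``/``feature_std`` hold the train-set per-pixel statistics
    when input standardisation is active; prediction re-applies them.
    """

    network: Network
    config: ModelConfig
    classes: np.ndarray  # class label per output index
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None


def build_model(config: ModelConfig) -> Network:
    """Assemble the (seeded, randomly initialised) network.

    ``use_pretrained_stem=True`` would initialise the stem from publicly
    distributed image-classification weights; no weight file is bundled with
    this package, so requesting it raises and seeded random initialisation
    is the supported path.
    """
    if config.use_pretrained_stem:
        raise ConfigurationError(
            "pretrained stem weights are not bundled; set use_pretrained_stem=False "
            "for seeded random initialisation"
        )
    rng = np.random.default_rng(config.seed)
    c_in = 3 if config.channel_mode == "replicate3" else 1
    s1, s2 = config.stem_filters
    layers = [
        Conv2d(c_in, s1, rng), ReLU(),
        Conv2d(s1, s1, rng), ReLU(),
        MaxPool2(),
        Conv2d(s1, s2, rng), ReLU(),
        Conv2d(s2, s2, rng), ReLU(),
        MaxPool2(),
    ]
    prev = s2
    for _ in range(config.core_conv_layers):
        layers += [Conv2d(prev, config.core_filters, rng), ReLU()]
        prev = config.core_filters
    layers += [
        MaxPool2(),
        GlobalAvgPool(),
        Dropout(config.dropout_core),
        Dense(prev, config.dense_units, rng), ReLU(),
        Dropout(config.dropout_head),
        Dense(config.dense_units, config.num_classes, rng),
    ]
    return Network(layers)


def _as_batch(images: np.ndarray, config: ModelConfig) -> np.ndarray:
    """GAF matrices (B, n, n) in [-1, 1] -> network input (B, n, n, C) float32."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != config.input_size or x.shape[2] != config.input_size:
        raise ValidationError(
            f"expected images of size {config.input_size}x{config.input_size}, "
            f"got {x.shape}"
        )
    if config.channel_mode == "replicate3":
        x01 = (x + 1.0) / 2.0  # map [-1, 1] to [0, 1] before replication
        return np.repeat(x01[..., None], 3, axis=3)
    return x[..., None]


def _labels_to_indices(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([lut[label] for label in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not among enrolled classes") from exc


def _eval_pass(network: Network, x: np.ndarray, y: np.ndarray, batch: int):
    losses, correct = [], 0
    for s in range(0, x.shape[0], batch):
        logits = network.forward(x[s : s + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[s : s + batch])
        losses.append(loss * (logits.shape[0]))
        correct += int((logits.argmax(axis=1) == y[s : s + batch]).sum())
    return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]


def train(
    network: Network,
    train_set: GAFDataset,
    val_set: GAFDataset,
    config: ModelConfig,
) -> tuple[TrainedModel, TrainingHistory]:
    """Optimise cross-entropy with Adam, early-stopping on validation loss.

    Stops once validation loss has failed to improve for
    ``early_stop_patience`` epochs and restores the best epoch's weights.
    Data order, initialisation and dropout are all driven by ``config.seed``.
    """
    classes = train_set.classes
    if classes.size != config.num_classes:
        raise ValidationError(
            f"training set has {classes.size} classes but the model expects "
            f"{config.num_classes}"
        )
    extra = set(np.unique(val_set.labels)) - set(classes)
    if extra:
        raise ValidationError(f"validation classes absent from training set: {sorted(extra)}")

    x_train = _as_batch(train_set.images, config)
    y_train = _labels_to_indices(train_set.labels, classes)
    x_val = _as_batch(val_set.images, config)
    y_val = _labels_to_indices(val_set.labels, classes)

    feature_mean = feature_std = None
    if config.standardize_inputs:
        feature_mean = x_train.mean(axis=0, keepdims=True)
        feature_std = x_train.std(axis=0, keepdims=True) + np.float32(1e-6)
        x_train = (x_train - feature_mean) / feature_std
        x_val = (x_val - feature_mean) / feature_std

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    optimizer = Adam(network, config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_weights = network.get_weights()
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_train.shape[0])
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, order.size, config.batch_size):
            sel = order[s : s + config.batch_size]
            x_batch = x_train[sel]
            if config.augment_time_shift:
                # a circular shift of the window is a joint row/column roll
                # of its Gramian; teaches shift invariance along the diagonal
                shifts = rng.integers(0, x_batch.shape[1], size=sel.size)
                x_batch = np.stack(
                    [np.roll(im, (k, k), axis=(0, 1)) for im, k in zip(x_batch, shifts)]
                )
            logits = network.forward(x_batch, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_train[sel])
            network.backward(dlogits.astype(np.float32))
            optimizer.step()
            ep_loss += loss * sel.size
            ep_correct += int((logits.argmax(axis=1) == y_train[sel]).sum())
        val_loss, val_acc = _eval_pass(network, x_val, y_val, config.batch_size)
        history.train_loss.append(ep_loss / order.size)
        history.train_accuracy.append(ep_correct / order.size)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.stopped_epoch = epoch

        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_weights = network.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.early_stop_patience:
                break
            if (
                config.lr_decay_patience > 0
                and since_best % config.lr_decay_patience == 0
            ):
                optimizer.lr *= config.lr_decay_factor

    network.set_weights(best_weights)
    trained = TrainedModel(network, config, classes, feature_mean, feature_std)
    return trained, history


def predict(trained: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Per-class probability matrix (rows sum to 1); deterministic inference."""
    x = _as_batch(images, trained.config)
    if trained.feature_mean is not None:
        x = (x - trained.feature_mean) / trained.feature_std
    probs = []
    for s in range(0, x.shape[0], trained.config.batch_size):
        logits = trained.network.forward(x[s : s + trained.config.batch_size], train=False)
        probs.append(softmax(logits.astype(np.float64)))
    return np.concatenate(probs, axis=0)


def save_model(trained: TrainedModel, history: TrainingHistory, out_dir: str | Path) -> Path:
    """Persist weights (npz), config (json) and training history (csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = trained.network.get_weights()
    if trained.feature_mean is not None:
        payload["stats.mean"] = trained.feature_mean
        payload["stats.std"] = trained.feature_std
    np.savez_compressed(out / "weights.npz", **payload)
    cfg = asdict(trained.config)
    cfg["stem_filters"] = list(cfg["stem_filters"])
    cfg["classes"] = [str(c) for c in trained.classes]
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    history.to_frame().to_csv(out / "history.csv", index=False)
    return out


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    cfg = json.loads((model_dir / "config.json").read_text())
    classes = np.asarray(cfg.pop("classes"))
    cfg["stem_filters"] = tuple(cfg["stem_filters"])
    config = ModelConfig(**cfg)
    network = build_model(config)
    with np.load(model_dir / "weights.npz") as z:
        payload = {k: z[k] for k in z.files}
    mean = payload.pop("stats.mean", None)
    std = payload.pop("stats.std", None)
    network.set_weights(payload)
    return TrainedModel(network, config, classes, mean, std)
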