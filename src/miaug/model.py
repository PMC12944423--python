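"""EEGNet: compact two-block convolutional classifier for EEG epochs.

Block 1 performs temporal filtering (F1 filters, 1×64 kernel, same padding),
then a depthwise spatial convolution spanning all electrodes (depth
multiplier D, giving F1·D = 16 feature maps), batch norm, ELU, 1×4 average
pooling and dropout.  Block 2 applies a plain 1×16 convolution with F2
filters, batch norm, ELU, 1×8 average pooling and dropout.  The flattened
features feed a fully connected output layer.  For the default 64-channel,
640-sample input the temporal dimension shrinks 640 → 160 → 20 and the
flattened vector has length F2 · 20 = 320.

Training uses Adam (lr 0.001), categorical cross-entropy, batch size 32, and
early stopping on *training* loss with a patience of 50 epochs, restoring the
weights of the best epoch.  Training without a validation split is unusual
but deliberate here: the benchmark treats the held-out test partition as
strictly untouchable, so model selection may only look at the training side.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import CLASSES, EpochSet

__all__ = [
    "EEGNetConfig",
    "ShapeTrace",
    "TrainResult",
    "EEGNet",
    "build_model",
    "shape_trace",
    "train",
    "predict",
    "scaled_down_config",
]


@dataclass
class EEGNetConfig:
    """Architecture and training hyperparameters (defaults: full-size model)."""

    n_channels: int = 64
    n_samples: int = 640
    F1: int = 8  # temporal filters
    temporal_kernel: int = 64
    D: int = 2  # depth multiplier of the spatial convolution
    F2: int = 16  # second-block filters
    second_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    n_classes: int = 3
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples % self.pool1 or (self.n_samples // self.pool1) % self.pool2:
            raise ValueError(
                f"n_samples={self.n_samples} must be divisible by pool1*pool2={self.pool1}*{self.pool2}"
            )
        if min(self.F1, self.D, self.F2, self.n_classes, self.temporal_kernel, self.second_kernel) < 1:
            raise ValueError("all architecture counts must be >= 1")

    @property
    def flatten_size(self) -> int:
        return self.F2 * (self.n_samples // (self.pool1 * self.pool2))


@dataclass
class ShapeTrace:
    """Layer-by-layer output dimensions of one forward pass."""

    stages: list[tuple[str, tuple[int, ...]]]

    @property
    def flattened_length(self) -> int:
        return int(np.prod(self.stages[-2][1])) if len(self.stages) >= 2 else 0

    def stage(self, name: str) -> tuple[int, ...]:
        for n, shape in self.stages:
            if n == name:
                return shape
        raise KeyError(name)


@dataclass
class TrainResult:
    loss_trace: list[float]
    best_epoch: int  # index into loss_trace of the restored weights
    restored: bool
    wall_time_s: float
    seed: int = 0


def scaled_down_config(max_epochs: int = 20, seed: int = 0, **overrides) -> EEGNetConfig:
    """A proportionally scaled EEGNet for 8-channel, 128-sample epochs.

    Used by the package's own desk-scale benchmarks: the temporal kernel
    shrinks with the epoch (16 samples = 0.1 s at 160 Hz), pooling still
    reduces time by 32×, and dropout is lowered to 0.25 because the model
    sees far fewer training epochs than at full scale.  All remaining
    hyperparameters keep their full-scale values.
    """
    base = dict(
        n_channels=8,
        n_samples=128,
        temporal_kernel=16,
        second_kernel=16,
        pool1=4,
        pool2=8,
        dropout=0.25,
        max_epochs=max_epochs,
        patience=50,
        seed=seed,
    )
    base.update(overrides)
    return EEGNetConfig(**base)


class EEGNet:
    """A built EEGNet instance (weights + config)."""

    def __init__(self, config: EEGNetConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x33]))
        c = config
        self.net = nn.Sequential([
            nn.TemporalConv(1, c.F1, c.temporal_kernel, rng),
            nn.BatchNorm(c.F1),
            nn.DepthwiseSpatialConv(c.F1, c.D, c.n_channels, rng),
            nn.BatchNorm(c.F1 * c.D),
            nn.ELU(),
            nn.AvgPoolTime(c.pool1),
            nn.Dropout(c.dropout),
            nn.TemporalConv(c.F1 * c.D, c.F2, c.second_kernel, rng),
            nn.BatchNorm(c.F2),
            nn.ELU(),
            nn.AvgPoolTime(c.pool2),
            nn.Dropout(c.dropout),
            nn.Flatten(),
            nn.Dense(c.flatten_size, c.n_classes, rng),
        ])
        self.classes = CLASSES[: c.n_classes]

    # ------------------------------------------------------------------
    def _prepare(self, data: np.ndarray) -> np.ndarray:
        x = np.asarray(data, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        return x[:, None, :, :]  # (N, 1, C, T)

    def logits(self, data: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.net.forward(self._prepare(data), train, rng)

    def observed_trace(self) -> ShapeTrace:
        """Shapes from an actual forward pass on a zero-valued epoch."""
        x = np.zeros((1, 1, self.config.n_channels, self.config.n_samples), dtype=nn.DTYPE)
        return ShapeTrace(self.net.forward_trace(x))


def build_model(config: EEGNetConfig) -> EEGNet:
    """Instantiate EEGNet with seeded weight initialization."""
    return EEGNet(config)


def shape_trace(config: EEGNetConfig) -> ShapeTrace:
    """Symbolic layer-by-layer shape record (no weights needed).

    The result is asserted equal to a real forward pass in the test suite;
    the two computations are independent (arithmetic here, arrays there).
    """
    c = config
    t = c.n_samples
    stages: list[tuple[str, tuple[int, ...]]] = [
        ("TemporalConv", (c.F1, c.n_channels, t)),
        ("BatchNorm", (c.F1, c.n_channels, t)),
        ("DepthwiseSpatialConv", (c.F1 * c.D, 1, t)),
        ("BatchNorm", (c.F1 * c.D, 1, t)),
        ("ELU", (c.F1 * c.D, 1, t)),
    ]
    t //= c.pool1
    stages += [
        ("AvgPoolTime", (c.F1 * c.D, 1, t)),
        ("Dropout", (c.F1 * c.D, 1, t)),
        ("TemporalConv", (c.F2, 1, t)),
        ("BatchNorm", (c.F2, 1, t)),
        ("ELU", (c.F2, 1, t)),
    ]
    t //= c.pool2
    stages += [
        ("AvgPoolTime", (c.F2, 1, t)),
        ("Dropout", (c.F2, 1, t)),
        ("Flatten", (c.F2 * t,)),
        ("Dense", (c.n_classes,)),
    ]
    return ShapeTrace(stages)


def train(model: EEGNet, train_set: EpochSet, config: EEGNetConfig | None = None) -> TrainResult:
    """Train ``model`` on ``train_set`` with Adam + early stopping.

    Fully seeded (initialization happens at build time; shuffling and
    dropout here), so the same seed yields an identical loss trace on the
    same backend.  Stops once the training loss has not improved for
    ``patience`` consecutive epochs and restores the best weights.
    """
    cfg = config or model.config
    if train_set.n_epochs == 0:
        raise ValueError("training set is empty")
    extra = set(train_set.labels) - set(model.classes)
    if extra:
        raise ValueError(f"labels {sorted(map(str, extra))} not covered by model classes {model.classes}")

    x = model._prepare(train_set.data)
    y = np.array([model.classes.index(l) for l in train_set.labels], dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x77]))
    opt = nn.Adam(model.net.all_params, model.net.all_grads, lr=cfg.learning_rate)

    t0 = time.perf_counter()
    losses: list[float] = []
    best_loss = np.inf
    best_epoch = -1
    best_state: list[np.ndarray] | None = None
    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.net.forward(x[idx], True, rng)
            loss, dz = nn.softmax_xent(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss became non-finite at epoch {epoch}")
            model.net.backward(dz)
            opt.step()
            total += loss * idx.size
        epoch_loss = total / n
        losses.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_epoch = epoch
            best_state = model.net.state()
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.net.load_state(best_state)
    return TrainResult(
        loss_trace=losses,
        best_epoch=best_epoch,
        restored=best_state is not None,
        wall_time_s=time.perf_counter() - t0,
        seed=cfg.seed,
    )


def predict(model: EEGNet, epochs: EpochSet | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and raw class scores (dropout off, running BN stats)."""
    data = epochs.data if isinstance(epochs, EpochSet) else epochs
    scores = model.logits(data, train=False)
    labels = np.array([model.classes[i] for i in scores.argmax(axis=1)], dtype=object)
    return labels, scores
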