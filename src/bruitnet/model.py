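"""The CBAM-LSTM shunt-sound classifier.

Architecture: three blocks of [3x3 conv -> LeakyReLU -> BatchNorm -> CBAM ->
2x2 max-pool -> dropout] with 64/128/256 filters, then a reshape of the
(C, 16, 17) map into a 16-step sequence (time-major, C*17 features per
step), an LSTM, a dense LeakyReLU layer with dropout, and a single sigmoid
output unit.  Trained with Adam (lr 0.001) on binary cross-entropy, batch
size 64, up to 300 epochs with early stopping on validation loss.

Implemented on the package's numpy autodiff core (:mod:`bruitnet.nn`);
training is single-threaded and bit-deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .features import N_FRAMES, N_MELS, N_MFCC

INPUT_SHAPE = (N_FRAMES, N_MELS + N_MFCC, 1)  # (128, 141, 1)


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the published training setup."""

    conv_filters: tuple[int, int, int] = (64, 128, 256)
    conv_kernel: int = 3
    leaky_slope: float = 0.01
    dropout_rate: float = 0.3
    cbam_reduction: int = 16
    cbam_kernel: int = 7
    lstm_units: int = 128
    dense_units: int = 64
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 300
    early_stop_patience: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.cbam_kernel % 2 == 0:
            raise ValueError("cbam_kernel must be odd")
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        if len(self.conv_filters) != 3:
            raise ValueError("conv_filters must have three entries")


@dataclass
class TrainingTrace:
    """Per-epoch loss/accuracy history plus the early-stop epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


class EarlyStopper:
    """Stop when validation loss has not improved for ``patience`` epochs.

    ``update`` returns True when training should halt; ``improved`` flags
    whether the last update set a new best (by more than ``min_delta``).
    """

    def __init__(self, patience: int, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0
        self.improved = False

    def update(self, val_loss: float) -> bool:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stale = 0
            self.improved = True
            return False
        self.improved = False
        self.stale += 1
        return self.stale >= self.patience


def binary_cross_entropy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean negative log-likelihood L = -1/N sum y log p + (1-y) log(1-p).

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the log.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class CbamLstmNet(nn.Module):
    """The classifier network; ``forward`` maps (N,128,141,1) -> (N,1)."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int, int] = INPUT_SHAPE):
        super().__init__()
        if tuple(input_shape) != INPUT_SHAPE:
            raise ValueError(f"expected input shape {INPUT_SHAPE}, got {tuple(input_shape)}")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

        h, w = input_shape[0], input_shape[1]
        in_ch = input_shape[2]
        self.blocks: list[dict] = []
        for k, filters in enumerate(config.conv_filters):
            reduction = min(config.cbam_reduction, filters)
            block = {
                "conv": self.add_child(f"conv{k}", nn.Conv2d(in_ch, filters, config.conv_kernel, rng)),
                "bn": self.add_child(f"bn{k}", nn.BatchNorm2d(filters)),
                "cbam": self.add_child(f"cbam{k}", nn.CBAM(filters, reduction, config.cbam_kernel, rng)),
                "drop": self.add_child(f"drop{k}", nn.Dropout(config.dropout_rate, self.dropout_rng)),
            }
            self.blocks.append(block)
            in_ch = filters
            h, w = h // 2, w // 2
        self.seq_steps, self.seq_width = h, w  # (16, 17) after three 2x2 pools
        lstm_in = config.conv_filters[-1] * w
        self.lstm = self.add_child("lstm", nn.LSTM(lstm_in, config.lstm_units, rng))
        self.fc1 = self.add_child("fc1", nn.Dense(config.lstm_units, config.dense_units, rng))
        self.drop_fc = self.add_child("drop_fc", nn.Dropout(config.dropout_rate, self.dropout_rng))
        self.fc2 = self.add_child("fc2", nn.Dense(config.dense_units, 1, rng))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """x: (N, time=128, feature=141, 1) -> probabilities (N, 1)."""
        n = x.shape[0]
        # to NCHW with time as height
        h = x.transpose((0, 3, 1, 2))
        slope = self.config.leaky_slope
        for block in self.blocks:
            h = block["conv"](h).leaky_relu(slope)
            h = block["bn"](h)
            h = block["cbam"](h)
            h = nn.max_pool2d(h, 2)
            h = block["drop"](h)
        # (N, C, T, W) -> sequence (N, T, C*W), time-major steps
        c = self.config.conv_filters[-1]
        seq = h.transpose((0, 2, 1, 3)).reshape(n, self.seq_steps, c * self.seq_width)
        hidden = self.lstm(seq)
        out = self.drop_fc(self.fc1(hidden).leaky_relu(slope))
        return self.fc2(out).sigmoid()

    __call__ = forward


def build_model(config: ModelConfig, input_shape: tuple[int, int, int] = INPUT_SHAPE) -> CbamLstmNet:
    """Construct a seeded, untrained classifier."""
    return CbamLstmNet(config, input_shape)


def _model_dtype(model: CbamLstmNet):
    return model.parameters()[0][1].data.dtype


def _forward_probs(model: CbamLstmNet, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Inference-mode probabilities for a feature array (N,128,141,1)."""
    model.set_training(False)
    dtype = _model_dtype(model)
    probs = []
    for lo in range(0, len(x), batch_size):
        out = model(nn.Tensor(np.asarray(x[lo : lo + batch_size], dtype=dtype)))
        probs.append(out.data.astype(np.float64).ravel())
    return np.concatenate(probs) if probs else np.zeros(0)


def _bce_loss_tensor(probs: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    p = probs.reshape(len(y)).clamp(1e-7, 1 - 1e-7)
    yt = nn.Tensor(y.astype(p.data.dtype))
    ll = yt * p.log() + (1.0 - yt) * (1.0 - p).log()
    return -ll.mean()


def train(
    model: CbamLstmNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainingTrace:
    """Fit with Adam + early stopping; restores best-validation parameters.

    ``train_y``/``val_y`` are 0/1 arrays (1 = abnormal).  Batch order is
    reshuffled each epoch from a seeded generator; the whole run is
    deterministic given ``config.seed``.
    """
    config = config or model.config
    for name, y in (("training", train_y), ("validation", val_y)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    # single-precision training: halves memory traffic; Adam moments stay f64
    model.set_dtype(np.float32)
    train_x = np.asarray(train_x, dtype=np.float32)
    val_x = np.asarray(val_x, dtype=np.float32)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    trace = TrainingTrace()
    stopper = EarlyStopper(config.early_stop_patience)
    best_state: dict | None = None

    for epoch in range(1, config.max_epochs + 1):
        model.set_training(True)
        order = rng.permutation(len(train_x))
        losses, hits, seen = [], 0, 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            model.zero_grad()
            probs = model(nn.Tensor(xb))
            loss = _bce_loss_tensor(probs, yb)
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data) * len(idx))
            hits += int(((probs.data.ravel() >= config.threshold) == (yb == 1)).sum())
            seen += len(idx)
        trace.train_loss.append(sum(losses) / seen)
        trace.train_accuracy.append(hits / seen)

        val_p = _forward_probs(model, val_x, config.batch_size)
        vloss = binary_cross_entropy(val_y, val_p)
        trace.val_loss.append(vloss)
        trace.val_accuracy.append(float(((val_p >= config.threshold) == (val_y == 1)).mean()))
        trace.stopped_epoch = epoch

        stop = stopper.update(vloss)
        if stopper.improved:
            best_state = model.state_dict()
        if stop:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return trace


def predict(
    model: CbamLstmNet,
    features: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1 = abnormal iff p >= threshold) and probabilities."""
    features = np.asarray(features)
    if features.ndim == 3:
        features = features[np.newaxis]
    if features.shape[1:] != INPUT_SHAPE:
        raise ValueError(f"expected features (N,)+{INPUT_SHAPE}, got {features.shape}")
    thr = model.config.threshold if threshold is None else threshold
    probs = _forward_probs(model, features, model.config.batch_size)
    return (probs >= thr).astype(np.int64), probs


def save_model(model: CbamLstmNet, directory: str | Path) -> None:
    """Persist config (JSON) and parameters/buffers (NPZ)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["conv_filters"] = list(cfg["conv_filters"])
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))
    np.savez(directory / "weights.npz", **model.state_dict())


def load_model(directory: str | Path) -> CbamLstmNet:
    """Rebuild a saved classifier; probabilities reproduce bit-identically."""
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    cfg["conv_filters"] = tuple(cfg["conv_filters"])
    model = build_model(ModelConfig(**cfg))
    with np.load(directory / "weights.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
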