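"""Image-based deep QC classifier.

The network ingests a 4-channel 3D volume -- the b=0 reference image
plus the x/y/z components of the directionally encoded color FA map --
and optionally a vector of 31 automated data-quality metrics routed
around the convolutional trunk.  Four conv blocks (64, 64, 128, 256
filters; kernel 3, pool 2, batch norm each) feed a global average
pool; the pooled features, concatenated with the standardized metrics
when present, pass through batch norm, two ReLU dense layers (512,
128) each followed by 40% dropout, and a single sigmoid unit.  The
metrics-augmented variant with 4 imaging channels and 31 metrics has
exactly 1,438,783 trainable parameters.

Training minimizes binary cross-entropy with Adam (initial learning
rate 1e-4), halves the learning rate when validation loss plateaus
for more than two epochs, and stops early when validation loss fails
to improve by more than 0.001 for twenty consecutive epochs, restoring
the best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hybridqc import nn

__all__ = [
    "QCNetworkSpec",
    "QCModel",
    "TrainingHistory",
    "build_qc_cnn",
    "train_qc_cnn",
    "train_qc_cnn_replicates",
    "predict_qc",
]

CONV_FILTERS = (64, 64, 128, 256)
DENSE_UNITS = (512, 128)
DROPOUT_RATE = 0.4


@dataclass(frozen=True)
class QCNetworkSpec:
    """Architecture description of the QC network.

    ``with_metrics`` selects the metrics-augmented variant.  Input
    spatial extents are configurable; each extent must survive four
    pooling halvings (multiple of 16).  Trainable parameter count is
    extent-invariant thanks to global average pooling.
    """

    with_metrics: bool = True
    n_imaging_channels: int = 4
    n_metrics: int = 31
    input_shape: tuple[int, int, int] = (32, 32, 32)

    def validate(self) -> None:
        if self.n_imaging_channels < 1:
            raise ValueError("need at least one imaging channel")
        if self.with_metrics and self.n_metrics < 1:
            raise ValueError("with_metrics requires n_metrics >= 1")
        for extent in self.input_shape:
            if extent < 16 or extent % 16:
                raise ValueError(
                    "each spatial extent must be a multiple of 16 (four "
                    f"pooling halvings); got {self.input_shape}"
                )


@dataclass
class TrainingHistory:
    """Per-epoch training curves and the stopping epoch."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    auc: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class QCModel:
    """The QC network with explicit forward/backward passes."""

    def __init__(self, spec: QCNetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        self.blocks = []
        c_in = spec.n_imaging_channels
        for f in CONV_FILTERS:
            self.blocks.append(
                [
                    nn.Conv3D(c_in, f, rng),
                    nn.ReLU(),
                    nn.MaxPool3D(),
                    nn.BatchNorm(f),
                ]
            )
            c_in = f
        self.gap = nn.GlobalAvgPool3D()

        head_in = CONV_FILTERS[-1] + (spec.n_metrics if spec.with_metrics else 0)
        self.head_bn = nn.BatchNorm(head_in)
        self.head = [
            nn.Dense(head_in, DENSE_UNITS[0], rng),
            nn.ReLU(),
            nn.Dropout(DROPOUT_RATE, self._dropout_rng),
            nn.Dense(DENSE_UNITS[0], DENSE_UNITS[1], rng),
            nn.ReLU(),
            nn.Dropout(DROPOUT_RATE, self._dropout_rng),
            nn.Dense(DENSE_UNITS[1], 1, rng),
        ]
        # Standardization constants for the metrics path (fit at train).
        self.metrics_mean = np.zeros(spec.n_metrics, dtype=np.float32)
        self.metrics_std = np.ones(spec.n_metrics, dtype=np.float32)

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> list[nn.Layer]:
        out = [layer for block in self.blocks for layer in block]
        out += [self.gap, self.head_bn] + self.head
        return out

    def count_parameters(self) -> int:
        """Trainable parameters: conv + dense weights/biases and batch-norm
        scale/shift; moving statistics excluded."""
        return int(sum(p.size for l in self.layers() for p in l.params()))

    def standardize_metrics(self, metrics: np.ndarray) -> np.ndarray:
        return (
            (metrics - self.metrics_mean) / self.metrics_std
        ).astype(np.float32)

    def fit_metrics_scaler(self, metrics: np.ndarray) -> None:
        self.metrics_mean = metrics.mean(axis=0).astype(np.float32)
        std = metrics.std(axis=0)
        self.metrics_std = np.where(std > 0, std, 1.0).astype(np.float32)

    # -- forward / backward ----------------------------------------------

    def forward_logits(
        self,
        volumes: np.ndarray,
        metrics: np.ndarray | None = None,
        training: bool = False,
    ) -> np.ndarray:
        if volumes.shape[1] != self.spec.n_imaging_channels:
            raise ValueError(
                f"expected {self.spec.n_imaging_channels} imaging channels, "
                f"got {volumes.shape[1]}"
            )
        if tuple(volumes.shape[2:]) != tuple(self.spec.input_shape):
            raise ValueError(
                f"expected spatial shape {self.spec.input_shape}, "
                f"got {tuple(volumes.shape[2:])}"
            )
        if self.spec.with_metrics:
            if metrics is None:
                raise ValueError("this model requires a metrics vector")
            if metrics.shape != (volumes.shape[0], self.spec.n_metrics):
                raise ValueError("metrics shape mismatch")

        # Channels-last internally (cache-friendly im2col); the public
        # interface stays channels-first.
        x = np.ascontiguousarray(
            np.moveaxis(volumes, 1, -1), dtype=np.float32
        )
        for block in self.blocks:
            for layer in block:
                x = layer.forward(x, training)
        x = self.gap.forward(x, training)
        if self.spec.with_metrics:
            self._n_pooled = x.shape[1]
            x = np.concatenate([x, self.standardize_metrics(metrics)], axis=1)
        x = self.head_bn.forward(x, training)
        for layer in self.head:
            x = layer.forward(x, training)
        return x[:, 0]

    def predict_proba(
        self,
        volumes: np.ndarray,
        metrics: np.ndarray | None = None,
        batch_size: int = 16,
    ) -> np.ndarray:
        out = []
        for start in range(0, volumes.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            m = metrics[sl] if metrics is not None else None
            out.append(nn.sigmoid(self.forward_logits(volumes[sl], m)))
        return np.concatenate(out)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop parameter gradients from d(loss)/d(logits)."""
        grad = dlogits[:, None].astype(np.float32)
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        grad = self.head_bn.backward(grad)
        if self.spec.with_metrics:
            grad = grad[:, : self._n_pooled]
        grad = self.gap.backward(grad)
        for block in reversed(self.blocks):
            for layer in reversed(block):
                grad = layer.backward(grad)

    def input_gradient(
        self,
        volumes: np.ndarray,
        metrics: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """d(sigmoid output)/d(input volume) and /d(metrics), inference mode.

        Raises if any gradient is non-finite.
        """
        logits = self.forward_logits(volumes, metrics, training=False)
        p = nn.sigmoid(logits)
        grad = (p * (1.0 - p))[:, None].astype(np.float32)
        for layer in reversed(self.head):
            if isinstance(layer, (nn.Dense, nn.Conv3D)):
                grad = layer.input_gradient_pass(grad)
            else:
                grad = layer.backward(grad)
        grad = self.head_bn.backward(grad)
        dmetrics = None
        if self.spec.with_metrics:
            dmetrics = grad[:, self._n_pooled :] / self.metrics_std
            grad = grad[:, : self._n_pooled]
        grad = self.gap.backward(grad)
        for block in reversed(self.blocks):
            for layer in reversed(block):
                if isinstance(layer, nn.Conv3D):
                    grad = layer.input_gradient_pass(grad)
                else:
                    grad = layer.backward(grad)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite input gradient")
        return np.moveaxis(grad, -1, 1), dmetrics

    # -- persistence ------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        weights = [p.copy() for l in self.layers() for p in l.params()]
        for l in self.layers():
            if isinstance(l, nn.BatchNorm):
                weights += [l.moving_mean.copy(), l.moving_var.copy()]
        weights += [self.metrics_mean.copy(), self.metrics_std.copy()]
        return weights

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers():
            for p in l.params():
                p[...] = weights[i]
                i += 1
        for l in self.layers():
            if isinstance(l, nn.BatchNorm):
                l.moving_mean[...] = weights[i]
                l.moving_var[...] = weights[i + 1]
                i += 2
        self.metrics_mean[...] = weights[i]
        self.metrics_std[...] = weights[i + 1]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *self.get_weights())
        spec = {
            "with_metrics": self.spec.with_metrics,
            "n_imaging_channels": self.spec.n_imaging_channels,
            "n_metrics": self.spec.n_metrics,
            "input_shape": list(self.spec.input_shape),
            "seed": self.seed,
        }
        (directory / "spec.json").write_text(json.dumps(spec, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "QCModel":
        directory = Path(directory)
        meta = json.loads((directory / "spec.json").read_text())
        spec = QCNetworkSpec(
            with_metrics=meta["with_metrics"],
            n_imaging_channels=meta["n_imaging_channels"],
            n_metrics=meta["n_metrics"],
            input_shape=tuple(meta["input_shape"]),
        )
        model = cls(spec, seed=meta["seed"])
        archive = np.load(directory / "weights.npz")
        model.set_weights([archive[k] for k in archive.files])
        return model


def build_qc_cnn(spec: QCNetworkSpec, seed: int = 0) -> QCModel:
    """Construct the QC network from its spec (validated)."""
    return QCModel(spec, seed=seed)


def _binary_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if np.unique(y).size < 2:
        return float("nan")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty_like(scores)
    ranks[order] = np.arange(1, len(scores) + 1)
    # midranks for ties
    s_sorted = scores[order]
    i = 0
    while i < len(s_sorted):
        j = i
        while j + 1 < len(s_sorted) and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def train_qc_cnn(
    model: QCModel,
    volumes: np.ndarray,
    targets: np.ndarray,
    metrics: np.ndarray | None = None,
    validation_fraction: float = 0.2,
    max_epochs: int = 100,
    batch_size: int = 8,
    initial_lr: float = 1e-4,
    lr_factor: float = 0.5,
    lr_patience: int = 2,
    early_stop_min_delta: float = 1e-3,
    early_stop_patience: int = 20,
    seed: int = 0,
) -> TrainingHistory:
    """Train the QC network in place and return its history.

    Continuous targets in [0, 1] are binarized at 0.5 for the binary
    cross-entropy objective.  Learning-rate plateau reduction and
    early stopping follow validation loss; the best-validation weights
    are restored at the end.
    """
    targets = np.asarray(targets, dtype=np.float64)
    y = (targets >= 0.5).astype(np.float64) if targets.max() <= 1 else targets
    if np.unique(y).size < 2:
        raise ValueError("need both classes among binarized targets")

    rng = np.random.default_rng(seed)
    n = volumes.shape[0]
    n_val = int(round(validation_fraction * n))
    if n_val < 1 or n_val >= n:
        raise ValueError("validation split empty or training split empty")
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if metrics is not None:
        model.fit_metrics_scaler(metrics[train_idx])

    optimizer = nn.Adam(model.layers(), lr=initial_lr)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    plateau_wait = 0
    stop_wait = 0

    for epoch in range(max_epochs):
        order = rng.permutation(train_idx)
        epoch_losses, epoch_probs, epoch_targets = [], [], []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            m = metrics[idx] if metrics is not None else None
            logits = model.forward_logits(volumes[idx], m, training=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            model.backward(dlogits)
            optimizer.step()
            epoch_losses.append(loss * len(idx))
            epoch_probs.append(nn.sigmoid(logits))
            epoch_targets.append(y[idx])

        # Running (pre-update) training metrics, Keras-style; validation
        # is a proper post-epoch pass.
        probs = np.concatenate(epoch_probs)
        targs = np.concatenate(epoch_targets)
        train_loss = float(np.sum(epoch_losses) / len(order))
        train_acc = float(((probs >= 0.5) == (targs == 1)).mean())
        train_auc = _binary_auc(targs, probs)

        m_val = metrics[val_idx] if metrics is not None else None
        val_proba = model.predict_proba(
            volumes[val_idx], m_val, batch_size=2 * batch_size
        )
        eps = 1e-7
        p = np.clip(val_proba, eps, 1 - eps)
        yv = y[val_idx]
        val_loss = float(-np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p)))
        val_acc = float(((val_proba >= 0.5) == (yv == 1)).mean())
        val_auc = _binary_auc(yv, val_proba)
        history.loss.append(train_loss)
        history.accuracy.append(train_acc)
        history.auc.append(train_auc)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.val_auc.append(val_auc)
        history.lr.append(optimizer.lr)

        if val_loss < best_val - early_stop_min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            stop_wait = 0
        else:
            stop_wait += 1

        # Plateau rule tracks its own best without the min-delta.
        if epoch > 0 and val_loss >= min(history.val_loss[:-1]):
            plateau_wait += 1
            if plateau_wait > lr_patience:
                optimizer.lr *= lr_factor
                plateau_wait = 0
        else:
            plateau_wait = 0

        if stop_wait >= early_stop_patience:
            break

    history.stopped_epoch = len(history.loss)
    model.set_weights(best_weights)
    return history


def train_qc_cnn_replicates(
    spec: QCNetworkSpec,
    volumes: np.ndarray,
    targets: np.ndarray,
    seeds: list[int],
    metrics: np.ndarray | None = None,
    **train_kwargs,
) -> tuple[list[QCModel], list[TrainingHistory]]:
    """Train one model per seed (distinct train/validation splits)."""
    models, histories = [], []
    for seed in seeds:
        model = build_qc_cnn(spec, seed=seed)
        history = train_qc_cnn(
            model, volumes, targets, metrics=metrics, seed=seed, **train_kwargs
        )
        models.append(model)
        histories.append(history)
    return models, histories


def predict_qc(
    models: QCModel | list[QCModel],
    volumes: np.ndarray,
    metrics: np.ndarray | None = None,
) -> np.ndarray:
    """QC score per participant; replicates combine by arithmetic mean."""
    if isinstance(models, QCModel):
        models = [models]
    probs = np.stack([m.predict_proba(volumes, metrics) for m in models], axis=0)
    return probs.mean(axis=0)
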