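"""The VGG-style 3D regression network and its training loop.

The reference architecture takes the normalized 3-channel 32^3 voxel grid of
a nucleotide environment and regresses its normalized unfitness score:

    input (3, 32^3)
      -> conv 8 @ 5^3  -> ReLU
      -> conv 16 @ 5^3 -> ReLU -> dropout 0.2
      -> maxpool 2 (stride 2)
      -> conv 32 @ 3^3 -> ReLU
      -> conv 64 @ 3^3 -> ReLU -> dropout 0.2
      -> flatten -> dense 128 -> ReLU -> dropout 0.2
      -> dense 1 (linear)

with stride-1 valid (unpadded) convolutions, giving the spatial trace
32 -> 28 -> 24 -> 12 -> 10 -> 8 and 4,282,801 trainable parameters.

Training minimizes mean squared error with plain mini-batch gradient
descent (batch 128, Glorot-uniform init, zero biases). The learning rate
starts at 0.05 and is halved whenever the validation MSE has not improved
for five consecutive epochs; training stops once the rate reaches
0.05 / 2^5 = 0.0015625 (or a max-epoch guard fires).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from . import _nn
from .errors import ModelError, ShapeError
from .featurize import NormalizationStats, VoxelGrid

logger = logging.getLogger(__name__)

#: forward/backward micro-batch size; bounds activation memory, not the SGD batch
_CHUNK = 16


@dataclass(frozen=True)
class ModelSpec:
    conv_filters: tuple[int, ...] = (8, 16, 32, 64)
    conv_kernels: tuple[int, ...] = (5, 5, 3, 3)
    pool_after_layer: int = 2  # 1-based conv index; 0 disables pooling
    pool_size: int = 2
    dense_units: int = 128
    output_units: int = 1
    dropout_layers: frozenset[str] = frozenset({"conv2", "conv4", "dense"})
    dropout_rate: float = 0.2
    input_channels: int = 3
    grid_edge: int = 32

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ModelError("conv_filters and conv_kernels must have equal length")
        if not 0 <= self.dropout_rate < 1:
            raise ModelError("dropout_rate must be in [0, 1)")

    @classmethod
    def reference(cls) -> "ModelSpec":
        """The full published architecture (4,282,801 parameters)."""
        return cls()

    @classmethod
    def desk_scale(cls) -> "ModelSpec":
        """Same layer topology, far fewer filters and all-3^3 kernels.

        Sized so a few hundred samples train in minutes on one CPU core;
        used by the synthetic end-to-end overfitting experiments, and
        therefore without dropout (a 0.2 rate on a 2-filter layer is
        crippling noise, and those experiments overfit deliberately).
        """
        return cls(conv_filters=(2, 2, 4, 4), conv_kernels=(3, 3, 3, 3),
                   dense_units=16, dropout_layers=frozenset())

    def shape_trace(self) -> list[int]:
        """Spatial edge length after the input and after each conv/pool."""
        trace = [self.grid_edge]
        size = self.grid_edge
        for i, k in enumerate(self.conv_kernels, start=1):
            size = size - k + 1
            if size < 1:
                raise ShapeError(
                    f"spatial size underflow at conv{i}: trace so far {trace}"
                )
            trace.append(size)
            if i == self.pool_after_layer:
                if size % self.pool_size:
                    raise ShapeError(
                        f"pool window {self.pool_size} does not tile size {size}"
                    )
                size //= self.pool_size
                trace.append(size)
        return trace

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        d["conv_kernels"] = list(self.conv_kernels)
        d["dropout_layers"] = sorted(self.dropout_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["conv_kernels"] = tuple(d["conv_kernels"])
        d["dropout_layers"] = frozenset(d["dropout_layers"])
        return cls(**d)


@dataclass
class TrainingSchedule:
    batch_size: int = 128
    initial_lr: float = 0.05
    lr_decay_factor: float = 0.5
    plateau_patience: int = 5
    stop_lr: float | None = None  # default: initial_lr * decay^5
    momentum: float = 0.0
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stop_lr is None:
            self.stop_lr = self.initial_lr * self.lr_decay_factor**5

    @classmethod
    def desk_scale(cls, seed: int = 0, max_epochs: int = 150) -> "TrainingSchedule":
        """Settings for overfitting a few hundred synthetic samples.

        The narrow desk-scale network diverges under the reference rate of
        0.05; a gentler 0.01 with momentum 0.9 converges below MSE 0.01
        within ~150 epochs.
        """
        return cls(initial_lr=0.01, momentum=0.9, max_epochs=max_epochs,
                   seed=seed)


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: _nn.Network
    normalization: NormalizationStats | None = None
    training_history: list[dict] = field(default_factory=list)


def build_model(spec: ModelSpec, seed: int = 0,
                dtype=np.float32) -> TrainedModel:
    """Instantiate the network with Glorot-uniform weights and zero biases."""
    trace = spec.shape_trace()  # validates the stack
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    c_in = spec.input_channels
    size = spec.grid_edge
    for i, (c_out, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels), start=1):
        layers.append(_nn.Conv3d(c_in, c_out, k, rng, dtype=dtype))
        layers.append(_nn.ReLU())
        if f"conv{i}" in spec.dropout_layers:
            layers.append(_nn.Dropout(spec.dropout_rate))
        size = size - k + 1
        if i == spec.pool_after_layer:
            layers.append(_nn.MaxPool3d(spec.pool_size))
            size //= spec.pool_size
        c_in = c_out
    layers.append(_nn.Flatten())
    n_features = c_in * size**3
    layers.append(_nn.Dense(n_features, spec.dense_units, rng, dtype=dtype))
    layers.append(_nn.ReLU())
    if "dense" in spec.dropout_layers:
        layers.append(_nn.Dropout(spec.dropout_rate))
    layers.append(_nn.Dense(spec.dense_units, spec.output_units, rng, dtype=dtype))
    logger.debug("built model: trace %s, %d parameters", trace,
                 sum(p.size for l in layers for p in l.params))
    return TrainedModel(spec=spec, network=_nn.Network(layers, dtype=dtype))


def count_parameters(model: TrainedModel) -> int:
    """Total number of trainable weights and biases."""
    return model.network.n_parameters()


def next_learning_rate(
    history: Sequence[float],
    current_lr: float,
    schedule: TrainingSchedule,
    last_reduction_epoch: int = -1,
) -> tuple[float, bool]:
    """Plateau-based learning-rate step.

    ``history`` is the per-epoch validation MSE so far (last entry = current
    epoch). A plateau means the best value has not strictly improved for
    ``plateau_patience`` consecutive epochs since the later of the best epoch
    and the last reduction. On plateau the rate is halved; ``stop`` becomes
    true once the rate reaches ``stop_lr``.
    """
    if not len(history):
        raise ModelError("history must be nonempty")
    arr = np.asarray(history, dtype=float)
    best_epoch = int(arr.argmin())  # first occurrence of the best value
    anchor = max(best_epoch, last_reduction_epoch)
    epochs_without_improvement = len(arr) - 1 - anchor
    if epochs_without_improvement >= schedule.plateau_patience:
        new_lr = current_lr * schedule.lr_decay_factor
        stop = new_lr <= schedule.stop_lr * (1 + 1e-12)
        return new_lr, stop
    return current_lr, False


def _materialize(samples) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays or an iterable of (VoxelGrid, label) pairs."""
    if isinstance(samples, tuple) and len(samples) == 2 \
            and isinstance(samples[0], np.ndarray):
        X, y = np.asarray(samples[0]), np.asarray(samples[1], dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise ModelError("labels must be normalized to [0, 1]")
        return X, y
    grids, labels = [], []
    for grid, label in samples:
        if isinstance(grid, VoxelGrid):
            if not grid.normalized:
                raise ModelError(
                    "training/validation grids must be normalized "
                    "(apply_normalization) before being fed to the network"
                )
            grids.append(grid.values)
        else:
            grids.append(np.asarray(grid))
        labels.append(float(label))
    if not grids:
        raise ModelError("empty sample stream")
    y = np.array(labels)
    if np.any((y < 0) | (y > 1)):
        raise ModelError("labels must be normalized to [0, 1]")
    return np.stack(grids), y


def _forward_chunked(network: _nn.Network, X: np.ndarray) -> np.ndarray:
    outs = [network.forward(X[i:i + _CHUNK]) for i in range(0, len(X), _CHUNK)]
    return np.concatenate(outs).ravel()


def train(
    model: TrainedModel,
    train_samples,
    val_samples,
    schedule: TrainingSchedule | None = None,
) -> TrainedModel:
    """Mini-batch SGD on the MSE loss with the plateau learning-rate schedule.

    ``train_samples``/``val_samples`` are iterables of
    ``(VoxelGrid, normalized label)`` pairs or pre-stacked ``(X, y)`` arrays.
    The model is updated in place and returned; per-epoch train/validation
    MSE and learning rate land in ``model.training_history``.
    """
    if schedule is None:
        schedule = TrainingSchedule()
    X, y = _materialize(train_samples)
    if val_samples is train_samples:
        Xv, yv = X, y
    else:
        Xv, yv = _materialize(val_samples)
    net = model.network
    rng = np.random.default_rng(schedule.seed)

    velocity = [np.zeros_like(p) for p, _ in net.parameters()] \
        if schedule.momentum else None
    lr = schedule.initial_lr
    last_reduction = -1
    val_history: list[float] = []

    for epoch in range(schedule.max_epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), schedule.batch_size):
            batch = order[start:start + schedule.batch_size]
            net.zero_grads()
            for cstart in range(0, len(batch), _CHUNK):
                idx = batch[cstart:cstart + _CHUNK]
                pred = net.forward(X[idx], training=True, rng=rng).ravel()
                grad = (2.0 / len(batch)) * (pred - y[idx])
                net.backward(grad[:, None], need_input_grad=False)
            for slot, (p, g) in enumerate(net.parameters()):
                if velocity is not None:
                    velocity[slot] = schedule.momentum * velocity[slot] - lr * g
                    p += velocity[slot]
                else:
                    p -= (lr * g).astype(p.dtype)

        train_mse = float(np.mean((_forward_chunked(net, X) - y) ** 2))
        if Xv is X:
            val_mse = train_mse  # validation stream is the training stream
        else:
            val_mse = float(np.mean((_forward_chunked(net, Xv) - yv) ** 2))
        val_history.append(val_mse)
        model.training_history.append(
            {"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse, "lr": lr}
        )
        new_lr, stop = next_learning_rate(val_history, lr, schedule, last_reduction)
        if new_lr != lr:
            last_reduction = epoch
            logger.info("epoch %d: lr %.6g -> %.6g (val MSE %.5f)",
                        epoch, lr, new_lr, val_mse)
            lr = new_lr
        if stop:
            break
    return model


def predict(model: TrainedModel,
            grid: Union[VoxelGrid, np.ndarray, Sequence]) -> Union[float, np.ndarray]:
    """Deterministic normalized unfitness score(s); dropout inactive.

    A single grid returns a float; a sequence/stack of grids returns an array
    of one score per grid, in order.
    """
    shape = (model.spec.input_channels,) + (model.spec.grid_edge,) * 3

    def _values(item) -> np.ndarray:
        if isinstance(item, VoxelGrid):
            if not item.normalized:
                raise ModelError("predict expects normalized grids")
            return item.values
        return np.asarray(item)

    if isinstance(grid, (list, tuple)):
        batch = np.stack([_values(item) for item in grid])
        single = False
    else:
        batch = _values(grid)
        single = batch.ndim == 4
        if single:
            batch = batch[None]
    if batch.ndim != 5 or batch.shape[1:] != shape:
        raise ModelError(f"expected grid shape {shape}, got {batch.shape[1:]}")
    scores = _forward_chunked(model.network, batch)
    return float(scores[0]) if single else scores


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Persist weights + spec + normalization + history to one .npz file."""
    arrays = {}
    for i, (p, _) in enumerate(model.network.parameters()):
        arrays[f"param_{i}"] = p
    header = {
        "spec": model.spec.to_dict(),
        "normalization": model.normalization.to_dict() if model.normalization else None,
        "training_history": model.training_history,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path: Union[str, Path]) -> TrainedModel:
    with np.load(str(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        model = build_model(ModelSpec.from_dict(header["spec"]))
        for i, (p, _) in enumerate(model.network.parameters()):
            stored = data[f"param_{i}"]
            if stored.shape != p.shape:
                raise ModelError(f"checkpoint parameter {i} has shape "
                                 f"{stored.shape}, expected {p.shape}")
            p[...] = stored
    if header["normalization"] is not None:
        model.normalization = NormalizationStats.from_dict(header["normalization"])
    model.training_history = header["training_history"]
    return model
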