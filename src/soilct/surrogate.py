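"""Surrogate-annotated regression training.

Every slice of a volume becomes one training sample: the input is a
3-channel image whose channels are the union masks of band pairs
(object1+2, object3+4, object5+6) and the target is the slice's trimmed
porosity for a chosen class selection. No manual labels exist anywhere;
the annotation is a pure function of the volume, which is the point of
the surrogate approach.

Models are VGG-style convolutional stacks with a dense head ending in a
single linear unit. ``scale="mini"`` is sized for CPU-scale synthetic
experiments; ``scale="full"`` reproduces the 16-layer reference topology
with the 1000-way classification layer replaced by one scalar output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .object_classes import (DEFAULT_CONNECTIVITY, DEFAULT_TRIM_MIN_SIZE,
                             ObjectClassScheme, annotate_volume, binarize)
from .volume_io import CTVolume

CHANNEL_BAND_PAIRS = ((1, 2), (3, 4), (5, 6))

__all__ = [
    "CHANNEL_BAND_PAIRS",
    "TrainingConfig",
    "TrainingDataset",
    "RegressionModel",
    "build_channel_image",
    "assemble_dataset",
    "split_dataset",
    "build_model",
    "train",
    "evaluate_rmse",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    patience: int = 10          # early stopping on held-out RMSE
    weight_decay: float = 0.0   # decoupled L2 on weight matrices
    seed: int = 0
    validation_fraction: float = 0.2  # carved from the training set when no
                                      # explicit validation set is passed


@dataclass
class TrainingDataset:
    """Index-aligned (channel image, porosity target) pairs."""

    images: np.ndarray                 # (N, Y, Z, 3) float32
    targets: np.ndarray                # (N,) float64 in [0, 1]
    target_classes: frozenset[int]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError(f"images must be (N,Y,Z,3), got {self.images.shape}")
        if self.targets.shape != (self.images.shape[0],):
            raise ValueError("one target per image required")
        if self.targets.size and (self.targets.min() < 0 or self.targets.max() > 1):
            raise ValueError("targets must lie in [0, 1]")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, indices) -> "TrainingDataset":
        indices = np.asarray(indices)
        return TrainingDataset(
            self.images[indices], self.targets[indices], self.target_classes,
            [self.provenance[i] for i in indices] if self.provenance else [])

    def with_targets(self, targets) -> "TrainingDataset":
        return TrainingDataset(self.images, targets, self.target_classes,
                               list(self.provenance))


class RegressionModel:
    """Conv stack + dense head with one scalar output.

    Wraps the Sequential stack with porosity-specific conveniences:
    predictions clipped to [0, 1] at inference, conv/dense layer
    grouping for transfer learning, and checkpointing.
    """

    def __init__(self, net: nn.Sequential, *, scale: str,
                 input_extents: tuple[int, int], seed: int):
        self.net = net
        self.scale = scale
        self.input_extents = tuple(input_extents)
        self.seed = seed
        self.fitted_metrics: dict[str, float] = {}

    # -- structure ---------------------------------------------------------
    @property
    def _flatten_index(self) -> int:
        for i, layer in enumerate(self.net.layers):
            if layer.kind == "flatten":
                return i
        raise ValueError("model has no flatten boundary between conv and dense")

    @property
    def conv_stack(self) -> list[nn.Layer]:
        return self.net.layers[:self._flatten_index]

    @property
    def dense_head(self) -> list[nn.Layer]:
        return [l for l in self.net.layers[self._flatten_index:]
                if l.kind == "dense"]

    def conv_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}:{l.name}:{k}": v.copy()
                for i, l in enumerate(self.conv_stack)
                for k, v in l.params.items()}

    def trainable_parameter_count(self) -> int:
        return self.net.trainable_parameter_count()

    # -- inference ---------------------------------------------------------
    def predict(self, images: np.ndarray, *, clip: bool = True,
                batch_size: int = 64) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        out = np.concatenate([
            self.net.forward(images[i:i + batch_size])
            for i in range(0, len(images), batch_size)])
        out = out[:, 0].astype(np.float64)
        return np.clip(out, 0.0, 1.0) if clip else out


def build_channel_image(volume: CTVolume, scheme: ObjectClassScheme,
                        slice_index: int, *, mode: str = "binary") -> np.ndarray:
    """3-channel (Y, Z, 3) image of one slice.

    Channel c is the union solid mask of its band pair under ``mode
    "binary"`` (default); ``mode "hu"`` instead scales the raw shifted-HU
    values within the pair's range into (0, 1], keeping 0 elsewhere.
    """
    if not 0 <= slice_index < volume.n_slices:
        raise IndexError(
            f"slice index {slice_index} out of range [0, {volume.n_slices})")
    channels = []
    plane = volume.voxels[slice_index]
    for pair in CHANNEL_BAND_PAIRS:
        mask = binarize(volume, pair, scheme).mask[slice_index]
        if mode == "binary":
            channels.append(mask.astype(np.float32))
        elif mode == "hu":
            lo = scheme.band(pair[0])[0]
            hi = scheme.band(pair[1])[1]
            scaled = (plane - lo + 1) / (hi - lo + 1)
            channels.append(np.where(mask, scaled, 0.0).astype(np.float32))
        else:
            raise ValueError(f"unknown channel mode {mode!r}")
    return np.stack(channels, axis=-1)


def assemble_dataset(volumes, scheme: ObjectClassScheme, target_classes,
                     trim_min_size: int = DEFAULT_TRIM_MIN_SIZE,
                     connectivity: int = DEFAULT_CONNECTIVITY,
                     *, mode: str = "binary") -> TrainingDataset:
    """One sample per slice of every volume; targets are trimmed porosities."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("at least one volume required")
    images, targets, provenance = [], [], []
    for volume in volumes:
        profile = annotate_volume(volume, scheme, target_classes,
                                  trim_min_size=trim_min_size,
                                  connectivity=connectivity)
        images.append(_channel_stack(volume, scheme, mode))
        targets.append(profile.values)
        provenance += [(volume.sample_id, i) for i in range(volume.n_slices)]
    return TrainingDataset(np.concatenate(images), np.concatenate(targets),
                           frozenset(int(c) for c in target_classes), provenance)


def _channel_stack(volume: CTVolume, scheme: ObjectClassScheme,
                   mode: str) -> np.ndarray:
    """All channel images of a volume at once: (X, Y, Z, 3)."""
    channels = [binarize(volume, pair, scheme).mask for pair in CHANNEL_BAND_PAIRS]
    if mode == "binary":
        return np.stack(channels, axis=-1).astype(np.float32)
    if mode == "hu":
        out = []
        for pair, mask in zip(CHANNEL_BAND_PAIRS, channels):
            lo = scheme.band(pair[0])[0]
            hi = scheme.band(pair[1])[1]
            scaled = (volume.voxels - lo + 1) / (hi - lo + 1)
            out.append(np.where(mask, scaled, 0.0))
        return np.stack(out, axis=-1).astype(np.float32)
    raise ValueError(f"unknown channel mode {mode!r}")


def split_dataset(dataset: TrainingDataset, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[TrainingDataset, TrainingDataset]:
    """Disjoint, exhaustive, seeded train/test split over slices."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


_FULL_BLOCKS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))
_MINI_BLOCKS = ((8, 2), (16, 1))


def build_model(input_extents: tuple[int, int], scale: str = "mini",
                seed: int = 0) -> RegressionModel:
    """Untrained regression CNN; final dense layer is a single linear unit."""
    if scale == "full":
        blocks, dense_widths = _FULL_BLOCKS, (4096, 4096)
    elif scale == "mini":
        blocks, dense_widths = _MINI_BLOCKS, (64,)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    h, w = input_extents
    if h % (2 ** len(blocks)) or w % (2 ** len(blocks)):
        raise ValueError(
            f"input extents {input_extents} not divisible by "
            f"2^{len(blocks)} pooling stages")

    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 3
    for b, (width, reps) in enumerate(blocks):
        for r in range(reps):
            layers.append(nn.Conv2D(in_ch, width, rng=rng,
                                    name=f"block{b + 1}_conv{r + 1}"))
            layers.append(nn.ReLU(name=f"block{b + 1}_relu{r + 1}"))
            in_ch = width
        layers.append(nn.MaxPool2D(name=f"block{b + 1}_pool"))
        h, w = h // 2, w // 2
    layers.append(nn.Flatten())
    in_features = h * w * in_ch
    for d, width in enumerate(dense_widths):
        layers.append(nn.Dense(in_features, width, rng=rng, name=f"fc{d + 1}"))
        layers.append(nn.ReLU(name=f"fc{d + 1}_relu"))
        in_features = width
    layers.append(nn.Dense(in_features, 1, rng=rng, name="output"))

    return RegressionModel(nn.Sequential(layers), scale=scale,
                           input_extents=input_extents, seed=seed)


def _rmse(pred: np.ndarray, targets: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - targets) ** 2)))


def train(model: RegressionModel, dataset: TrainingDataset,
          config: TrainingConfig = TrainingConfig(),
          validation: TrainingDataset | None = None
          ) -> tuple[RegressionModel, pd.DataFrame]:
    """Minimize MSE against the surrogate targets with early stopping.

    When no validation set is given, ``config.validation_fraction`` of
    the dataset is held out for the stopping criterion. Returns the model
    (restored to its best-validation weights) and the per-epoch history.
    """
    if validation is None:
        dataset, validation = split_dataset(
            dataset, 1.0 - config.validation_fraction, seed=config.seed)

    conv_frozen = model.conv_stack and all(
        not l.trainable for l in model.conv_stack)
    if conv_frozen:
        # dense-only training: push images through the frozen stack once
        # and iterate epochs over the cached features (identical math,
        # large speedup)
        boundary = model._flatten_index + 1
        net = nn.Sequential(model.net.layers[boundary:])
        x_train = _frozen_features(model, dataset.images)
        x_val = _frozen_features(model, validation.images)
    else:
        net = model.net
        x_train, x_val = dataset.images, validation.images

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(net, learning_rate=config.learning_rate,
                        weight_decay=config.weight_decay)

    def rmse_on(x, targets):
        pred = np.concatenate([net.forward(x[i:i + 64])
                               for i in range(0, len(x), 64)])[:, 0]
        return _rmse(np.clip(pred, 0.0, 1.0), targets)

    best_val = np.inf
    best_weights = net.get_weights()
    stale = 0
    rows = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            net.loss_and_backward(x_train[idx], dataset.targets[idx])
            optimizer.step()
        train_rmse = rmse_on(x_train, dataset.targets)
        val_rmse = rmse_on(x_val, validation.targets)
        rows.append({"epoch": epoch, "train_rmse": train_rmse,
                     "val_rmse": val_rmse})
        if val_rmse < best_val - 1e-6:
            best_val = val_rmse
            best_weights = net.get_weights()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    net.set_weights(best_weights)
    history = pd.DataFrame(rows)
    model.fitted_metrics = {"train_rmse": rows[-1]["train_rmse"] if rows else np.nan,
                            "val_rmse": best_val}
    return model, history


def _frozen_features(model: RegressionModel, images: np.ndarray,
                     batch_size: int = 64) -> np.ndarray:
    """Flattened conv-stack output for every image."""
    prefix = model.net.layers[:model._flatten_index + 1]
    chunks = []
    for i in range(0, len(images), batch_size):
        out = np.asarray(images[i:i + batch_size], dtype=np.float32)
        for layer in prefix:
            out = layer.forward(out)
        chunks.append(out)
    return np.concatenate(chunks)


def evaluate_rmse(model: RegressionModel, dataset: TrainingDataset) -> float:
    """Root mean squared error of the model's predictions on a dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    return _rmse(model.predict(dataset.images), dataset.targets)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: RegressionModel, path) -> None:
    meta = {"scale": model.scale, "input_extents": list(model.input_extents),
            "seed": model.seed, "fitted_metrics": model.fitted_metrics,
            "trainable": [l.trainable for l in model.net.layers]}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.net.get_weights())


def load_model(path) -> RegressionModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(tuple(meta["input_extents"]), scale=meta["scale"],
                        seed=meta["seed"])
    model.net.set_weights(weights)
    for layer, flag in zip(model.net.layers, meta["trainable"]):
        layer.trainable = bool(flag)
    model.fitted_metrics = meta.get("fitted_metrics", {})
    return model
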