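"""Minimal CNN engine (NHWC, float32) used by the regression models.

Implements only what the pipeline needs: 3x3 same-padding convolutions,
ReLU, 2x2 max pooling, dense layers, MSE loss with backprop, Adam, and
per-layer trainable flags so the convolutional stack can be frozen for
transfer learning. Written against numpy because no deep-learning
framework is available in the execution environment.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "save_weights_npz",
]


class Layer:
    """Base layer: forward caches whatever backward needs."""

    kind = "base"
    trainable = True

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def config(self) -> dict:
        return {"kind": self.kind, "name": self.name}


class Conv2D(Layer):
    """3x3 (or kxk, odd k) convolution with 'same' zero padding, stride 1."""

    kind = "conv"

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 *, rng: np.random.Generator, name: str = "conv"):
        super().__init__(name)
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = kernel_size * kernel_size * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init, ReLU follows every conv here
        self.params["W"] = (rng.standard_normal(
            (kernel_size, kernel_size, in_channels, out_channels)) * scale
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {c}")
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # sliding_window_view gives (n,h,w,c,k,k); flatten as (k,k,c) to match W
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(n * h * w, k * k * c)
        wm = self.params["W"].reshape(k * k * c, self.out_channels)
        out = cols @ wm + self.params["b"]
        self._cols = cols
        self._in_shape = (n, h, w, c)
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        n, h, w, c = self._in_shape
        dm = dout.reshape(n * h * w, self.out_channels)
        wm = self.params["W"].reshape(k * k * c, self.out_channels)
        self.grads["W"] = (self._cols.T @ dm).reshape(self.params["W"].shape)
        self.grads["b"] = dm.sum(axis=0)
        dcols = (dm @ wm.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad:pad + h, pad:pad + w, :]

    def config(self) -> dict:
        return {"kind": self.kind, "name": self.name,
                "in_channels": self.in_channels, "out_channels": self.out_channels,
                "kernel_size": self.kernel_size}


class ReLU(Layer):
    kind = "relu"
    trainable = False

    def __init__(self, name: str = "relu"):
        super().__init__(name)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; spatial extents must be even."""

    kind = "pool"
    trainable = False

    def __init__(self, name: str = "pool"):
        super().__init__(name)
        self._argmask: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: spatial extents must be even, got {(h, w)}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._argmask = idx
        self._in_shape = (n, h, w, c)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmask[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class Flatten(Layer):
    kind = "flatten"
    trainable = False

    def __init__(self, name: str = "flatten"):
        super().__init__(name)
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    kind = "dense"

    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, name: str = "dense"):
        super().__init__(name)
        self.in_features = in_features
        self.out_features = out_features
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = (rng.standard_normal((in_features, out_features)) * scale
                            ).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)
        self._x: np.ndarray | None = None

    def reinitialize(self, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / self.in_features)
        self.params["W"] = (rng.standard_normal((self.in_features, self.out_features))
                            * scale).astype(np.float32)
        self.params["b"] = np.zeros(self.out_features, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def config(self) -> dict:
        return {"kind": self.kind, "name": self.name,
                "in_features": self.in_features, "out_features": self.out_features}


class Sequential:
    """Ordered layer stack with MSE loss helpers and freeze support."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dout: np.ndarray, *, stop_after: int = 0) -> np.ndarray:
        """Backprop `dout` from the top; stops after layer index `stop_after`."""
        for layer in reversed(self.layers[stop_after:]):
            dout = layer.backward(dout)
        return dout

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean-squared-error loss; populates layer gradients."""
        pred = self.forward(x)
        y = np.asarray(y, dtype=np.float32).reshape(pred.shape)
        diff = pred - y
        loss = float(np.mean(diff ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}); predictions range "
                f"[{np.nanmin(pred)}, {np.nanmax(pred)}]")
        self.backward(2.0 * diff / diff.size)
        return loss

    # -- introspection -----------------------------------------------------
    def trainable_parameter_count(self) -> int:
        return sum(l.parameter_count() for l in self.layers if l.trainable)

    def parameter_count(self) -> int:
        return sum(l.parameter_count() for l in self.layers)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}:{l.name}:{k}": v.copy()
                for i, l in enumerate(self.layers) for k, v in l.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            for k in l.params:
                l.params[k] = weights[f"{i}:{l.name}:{k}"].copy()

    def config(self) -> list[dict]:
        return [l.config() for l in self.layers]


class Adam:
    """Adam over the trainable layers of a Sequential model."""

    def __init__(self, model: Sequential, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay  # decoupled (AdamW-style), W only
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, layer in enumerate(self.model.layers):
            if not layer.trainable:
                continue
            for k, g in layer.grads.items():
                key = (i, k)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(g)
                    self._v[key] = np.zeros_like(g)
                v = self._v[key]
                m[...] = self.beta1 * m + (1 - self.beta1) * g
                v[...] = self.beta2 * v + (1 - self.beta2) * g * g
                self._m[key] = m
                layer.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                if self.weight_decay and k == "W":
                    layer.params[k] -= self.lr * self.weight_decay * layer.params[k]


def save_weights_npz(model: Sequential, path) -> None:
    weights = model.get_weights()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config()).encode(), dtype=np.uint8), **weights)
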