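"""Grad-CAM for the scalar-output regression models.

Classic grad-CAM differentiates a class score; with a single-unit
regression head the scalar output itself is differentiated. For a chosen
convolutional layer, each activation map is weighted by the spatial mean
of the output's gradient with respect to it; the rectified weighted sum,
normalized by its maximum and bilinearly upsampled to the input extents,
is the heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from skimage.transform import resize

from .surrogate import RegressionModel

__all__ = ["HeatMap", "grad_cam", "overlay"]


@dataclass
class HeatMap:
    """Non-negative 2D map in [0, 1] at the input image's extents."""

    values: np.ndarray
    target_layer: str
    model_scale: str = ""
    slice_ref: tuple[str, int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("heatmap must be 2D")
        if self.values.size and self.values.min() < 0:
            raise ValueError("heatmap values must be >= 0")
        peak = self.values.max() if self.values.size else 0.0
        if peak > 0 and not np.isclose(peak, 1.0):
            raise ValueError("non-zero heatmaps must be max-normalized")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


def _conv_layer_index(model: RegressionModel, target_layer: str | None) -> int:
    conv_indices = [i for i, l in enumerate(model.net.layers) if l.kind == "conv"]
    if not conv_indices:
        raise ValueError("model has no convolutional layers")
    if target_layer is None:
        return conv_indices[-1]
    for i in conv_indices:
        if model.net.layers[i].name == target_layer:
            return i
    names = {model.net.layers[i].name for i in conv_indices}
    raise ValueError(
        f"no convolutional layer named {target_layer!r}; available: {sorted(names)}")


def grad_cam(model: RegressionModel, image: np.ndarray,
             target_layer: str | None = None) -> HeatMap:
    """Heatmap of the regions driving the scalar prediction for one image.

    `image` is one (Y, Z, 3) channel image; `target_layer` names a conv
    layer (default: the last one).
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError(f"expected one (Y, Z, 3) image, got shape {image.shape}")
    layer_index = _conv_layer_index(model, target_layer)

    x = image[None]
    out = x
    activations = None
    for i, layer in enumerate(model.net.layers):
        out = layer.forward(out)
        if i == layer_index:
            activations = out
    # d(output)/d(activation maps) via backprop stopped at the target layer
    grad = model.net.backward(np.ones((1, 1), dtype=np.float32),
                              stop_after=layer_index + 1)

    weights = grad[0].mean(axis=(0, 1))                   # one weight per map
    cam = np.maximum((activations[0] * weights).sum(axis=-1), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    cam = resize(cam, image.shape[:2], order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    cam = np.clip(cam, 0.0, None)
    if cam.max() > 0:
        cam = cam / cam.max()
    return HeatMap(cam, target_layer=model.net.layers[layer_index].name,
                   model_scale=model.scale)


def overlay(heatmap: HeatMap, image: np.ndarray, *, alpha_scale: float = 0.6,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the color-mapped heatmap over the grayscale slice.

    Blending weight is proportional to the local heatmap value, so a zero
    heatmap returns the base image unchanged. Output is (Y, Z, 3) RGB in
    [0, 1].
    """
    image = np.asarray(image, dtype=float)
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    if gray.shape != heatmap.values.shape:
        raise ValueError(
            f"extent mismatch: heatmap {heatmap.values.shape} vs image {gray.shape}")
    rng = gray.max() - gray.min()
    gray = (gray - gray.min()) / rng if rng > 0 else np.zeros_like(gray)
    base = np.stack([gray] * 3, axis=-1)
    colors = matplotlib.colormaps[cmap](heatmap.values)[..., :3]
    alpha = (alpha_scale * heatmap.values)[..., None]
    return (1 - alpha) * base + alpha * colors
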