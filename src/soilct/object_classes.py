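"""HU-band object classes, binarization, cluster trimming and porosity.

The shifted-HU range [0, 6144] is partitioned into contiguous "object
class" bands (default: six bands of width 1024, the top band absorbing
6144). Selecting one or more bands as the solid phase yields a binary
volume coded 0 = void, 1 = solid; porosity of a slice is then

    P = Area(void) / (Area(void) + Area(solid))

and the per-slice porosities along the core axis form the surrogate
annotation used for CNN training. Small solid clusters (default: fewer
than 60 voxels, 26-connectivity in 3D) are trimmed to void before
profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CTVolume, HU_MAX, HU_MIN

DEFAULT_TRIM_MIN_SIZE = 60
DEFAULT_CONNECTIVITY = 26

__all__ = [
    "ObjectClassScheme",
    "BinaryVolume",
    "PorosityProfile",
    "default_scheme",
    "classify_voxel",
    "classify_volume",
    "binarize",
    "trim_small_clusters",
    "slice_porosity",
    "porosity_profile",
    "annotate_volume",
    "DEFAULT_TRIM_MIN_SIZE",
    "DEFAULT_CONNECTIVITY",
]


@dataclass(frozen=True)
class ObjectClassScheme:
    """Ordered, disjoint, contiguous partition of [0, 6144] into bands."""

    bands: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.bands:
            raise ValueError("scheme needs at least one band")
        lo0 = self.bands[0][0]
        hiN = self.bands[-1][1]
        if lo0 != HU_MIN or hiN != HU_MAX:
            raise ValueError(
                f"bands must jointly cover [{HU_MIN}, {HU_MAX}], "
                f"got [{lo0}, {hiN}]")
        for (alo, ahi), (blo, bhi) in zip(self.bands, self.bands[1:]):
            if ahi + 1 != blo:
                raise ValueError(
                    f"bands must be contiguous and ascending; gap between "
                    f"[{alo},{ahi}] and [{blo},{bhi}]")
        for lo, hi in self.bands:
            if lo > hi:
                raise ValueError(f"empty band [{lo},{hi}]")

    @property
    def n_classes(self) -> int:
        return len(self.bands)

    def band(self, class_index: int) -> tuple[int, int]:
        """Inclusive (lo, hi) of the 1-based class."""
        if not 1 <= class_index <= self.n_classes:
            raise ValueError(f"unknown class index {class_index}")
        return self.bands[class_index - 1]

    def lows(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bands])


def default_scheme() -> ObjectClassScheme:
    """Six bands of width 1024: [0,1023] ... [5120,6144]."""
    bands = [(i * 1024, i * 1024 + 1023) for i in range(6)]
    bands[-1] = (5120, HU_MAX)
    return ObjectClassScheme(tuple(bands))


@dataclass
class BinaryVolume:
    """Void/solid mask: 0 = void, 1 = solid (selected object classes)."""

    mask: np.ndarray
    sample_id: str = "unknown"
    object_classes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got ndim={self.mask.ndim}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0/1, found {vals}")
        self.mask = self.mask.astype(np.uint8)

    def slice(self, index: int) -> "BinaryVolume":
        if self.mask.ndim != 3:
            raise ValueError("slice() requires a 3D mask")
        return BinaryVolume(self.mask[index], sample_id=self.sample_id,
                            object_classes=self.object_classes)


@dataclass
class PorosityProfile:
    """Per-slice porosity values along the core axis (X)."""

    values: np.ndarray
    object_classes: frozenset[int]
    sample_id: str = "unknown"
    slice_thickness_mm: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1D")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("porosity values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(len(self.values))
        return pd.DataFrame({
            "slice_index": idx,
            "depth_mm": idx * self.slice_thickness_mm,
            "porosity": self.values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_voxel(shifted_hu: int, scheme: ObjectClassScheme) -> int:
    """1-based index of the band containing a shifted-HU value."""
    if not HU_MIN <= shifted_hu <= HU_MAX:
        raise ValueError(f"value {shifted_hu} outside [{HU_MIN}, {HU_MAX}]")
    return int(np.searchsorted(scheme.lows(), shifted_hu, side="right"))


def classify_volume(volume: CTVolume, scheme: ObjectClassScheme) -> np.ndarray:
    """Per-voxel 1-based class indices (vectorized classify_voxel)."""
    return np.searchsorted(scheme.lows(), volume.voxels, side="right")


def binarize(volume: CTVolume, class_indices, scheme: ObjectClassScheme) -> BinaryVolume:
    """Mask with the selected object class(es) as solid (1), rest void (0)."""
    indices = frozenset(int(i) for i in class_indices)
    if not indices:
        raise ValueError("class_indices must be non-empty")
    for i in indices:
        scheme.band(i)  # raises on unknown index
    classes = classify_volume(volume, scheme)
    mask = np.isin(classes, sorted(indices)).astype(np.uint8)
    return BinaryVolume(mask, sample_id=volume.sample_id, object_classes=indices)


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity in (6, 4):       # faces only
        rank = 1
    elif connectivity in (26, 8):    # faces + edges + corners
        rank = ndim
    elif connectivity == 18 and ndim == 3:
        rank = 2
    else:
        raise ValueError(f"invalid connectivity {connectivity} for {ndim}D")
    return ndimage.generate_binary_structure(ndim, rank)


def trim_small_clusters(mask: BinaryVolume, min_size: int = DEFAULT_TRIM_MIN_SIZE,
                        connectivity: int = DEFAULT_CONNECTIVITY) -> BinaryVolume:
    """Reassign solid clusters with fewer than `min_size` voxels to void.

    Clusters with exactly `min_size` voxels survive ("fewer than"
    semantics). Connectivity 6 or 26 in 3D (4 or 8 in 2D).
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    structure = _structure(mask.mask.ndim, connectivity)
    labels, n = ndimage.label(mask.mask, structure=structure)
    if n == 0 or min_size == 1:
        return BinaryVolume(mask.mask.copy(), sample_id=mask.sample_id,
                            object_classes=mask.object_classes)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    trimmed = keep[labels].astype(np.uint8)
    return BinaryVolume(trimmed, sample_id=mask.sample_id,
                        object_classes=mask.object_classes)


def slice_porosity(slice_mask) -> float:
    """Void fraction of one slice: count(0) / (count(0) + count(1))."""
    arr = slice_mask.mask if isinstance(slice_mask, BinaryVolume) else np.asarray(slice_mask)
    if arr.size == 0:
        raise ValueError("zero-size slice")
    solid = int(arr.sum())
    total = int(arr.size)
    return (total - solid) / total


def porosity_profile(mask: BinaryVolume) -> PorosityProfile:
    """Per-X-plane porosity of a 3D mask."""
    if mask.mask.ndim != 3:
        raise ValueError("porosity_profile needs a 3D mask")
    solid = mask.mask.sum(axis=(1, 2), dtype=np.int64)
    total = mask.mask.shape[1] * mask.mask.shape[2]
    return PorosityProfile((total - solid) / total,
                           object_classes=mask.object_classes,
                           sample_id=mask.sample_id)


def annotate_volume(volume: CTVolume, scheme: ObjectClassScheme, target_classes,
                    trim_min_size: int = DEFAULT_TRIM_MIN_SIZE,
                    connectivity: int = DEFAULT_CONNECTIVITY) -> PorosityProfile:
    """binarize -> trim_small_clusters -> porosity_profile (the surrogate
    annotation for one volume and one target-class selection)."""
    mask = binarize(volume, target_classes, scheme)
    mask = trim_small_clusters(mask, min_size=trim_min_size,
                               connectivity=connectivity)
    profile = porosity_profile(mask)
    profile.slice_thickness_mm = volume.spacing[0]
    return profile
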