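"""Reading, shifting and cropping CT soil-core volumes.

A volume is a 3D integer grid in shifted Hounsfield units, oriented
(X, Y, Z) with slices taken along X (the core depth axis). Raw scanner
values in [-2048, 4096] HU are shifted by +2048 into [0, 6144];
out-of-range values are clamped so stray scanner readings cannot abort
a run. Analysis uses the centered inner region (default 400x200x200)
to avoid edge effects from the sampling cylinder.

DICOM I/O is handled by a small explicit-VR little-endian codec in
:mod:`soilct.dicom_lite` (no DICOM library is available at runtime);
:func:`write_dicom_series` exists so synthetic volumes can round-trip
through the standard on-disk format in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dicom_lite

HU_SHIFT = 2048
HU_MIN = 0
HU_MAX = 6144
DEFAULT_CROP = (400, 200, 200)

__all__ = [
    "CTVolume",
    "shift_hu",
    "crop_inner",
    "read_dicom_series",
    "write_dicom_series",
    "read_raw_volume",
    "write_raw_volume",
    "HU_SHIFT",
    "HU_MIN",
    "HU_MAX",
    "DEFAULT_CROP",
]


@dataclass
class CTVolume:
    """3D voxel grid in shifted-HU units with spacing metadata.

    Attributes
    ----------
    voxels : numpy.ndarray
        Integer array indexed (X, Y, Z); values in [0, 6144].
    spacing : tuple of float
        (slice_thickness_mm, y_mm, z_mm), all > 0.
    sample_id : str
        Opaque label for provenance tracking.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.25, 0.351, 0.351)
    sample_id: str = field(default="unknown")

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError(f"voxels must be integer-typed, got {self.voxels.dtype}")
        if any(e < 1 for e in self.voxels.shape):
            raise ValueError(f"all extents must be >= 1, got {self.voxels.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing values must be > 0, got {self.spacing}")
        if self.voxels.size:
            lo, hi = int(self.voxels.min()), int(self.voxels.max())
            if lo < HU_MIN or hi > HU_MAX:
                raise ValueError(
                    f"voxel values [{lo}, {hi}] outside shifted-HU range "
                    f"[{HU_MIN}, {HU_MAX}]")

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_depth_mm(self, index: int) -> float:
        return index * self.spacing[0]


def shift_hu(raw_hu):
    """Shift raw HU by +2048 and clamp into [0, 6144].

    Accepts scalars or arrays; always returns integer-typed output.
    """
    shifted = np.asarray(raw_hu, dtype=np.int64) + HU_SHIFT
    clamped = np.clip(shifted, HU_MIN, HU_MAX)
    if np.isscalar(raw_hu) or np.ndim(raw_hu) == 0:
        return int(clamped)
    return clamped


def crop_inner(volume: CTVolume,
               target_extents: tuple[int, int, int] = DEFAULT_CROP) -> CTVolume:
    """Centered sub-volume with the requested extents.

    For odd differences the lower offset takes the floor, so cropping an
    already-cropped volume to the same extents is the identity.
    """
    src = volume.voxels.shape
    if len(target_extents) != 3:
        raise ValueError("target_extents must have three components")
    for axis, (t, s) in enumerate(zip(target_extents, src)):
        if t < 1:
            raise ValueError(f"target extent on axis {axis} must be >= 1, got {t}")
        if t > s:
            raise ValueError(
                f"target extent {t} exceeds source extent {s} on axis {axis}")
    offsets = [(s - t) // 2 for s, t in zip(src, target_extents)]
    sl = tuple(slice(o, o + t) for o, t in zip(offsets, target_extents))
    return CTVolume(volume.voxels[sl].copy(), spacing=volume.spacing,
                    sample_id=volume.sample_id)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory_path) -> CTVolume:
    """Read a single-series DICOM directory into a shifted-HU volume.

    Slices are sorted into ascending position along the core axis, the
    per-slice rescale slope/intercept is applied (identity when absent),
    and the result is shifted with :func:`shift_hu`.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no DICOM (.dcm) files in {directory}")

    slices = [dicom_lite.read_slice(p) for p in files]

    shapes = {s.pixels.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice dimensions across series: {shapes}")
    positions = [s.position for s in slices]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate slice positions in series")
    order = np.argsort(positions, kind="stable")

    first = slices[order[0]]
    raw = np.stack([slices[i].pixels for i in order]).astype(np.int64)
    hu = raw * first.rescale_slope + first.rescale_intercept
    voxels = shift_hu(np.rint(hu).astype(np.int64))
    spacing = (first.slice_spacing, first.pixel_spacing[0], first.pixel_spacing[1])
    return CTVolume(voxels, spacing=spacing, sample_id=first.series_id or directory.name)


def write_dicom_series(volume: CTVolume, directory_path) -> list[Path]:
    """Export a volume as one .dcm file per X-slice (test/e2e helper).

    Stored pixel values are raw HU (shifted value minus 2048) as signed
    16-bit with identity rescale, so read_dicom_series round-trips
    voxels bit-exactly.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    raw = volume.voxels.astype(np.int64) - HU_SHIFT
    paths = []
    for i in range(volume.n_slices):
        path = directory / f"slice_{i:04d}.dcm"
        dicom_lite.write_slice(
            path,
            raw[i].astype(np.int16),
            instance_number=i + 1,
            position=i * volume.spacing[0],
            slice_spacing=volume.spacing[0],
            pixel_spacing=(volume.spacing[1], volume.spacing[2]),
            series_id=volume.sample_id,
        )
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Raw fixture format: headerless voxel stream + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(file_path: Path) -> Path:
    return file_path.with_suffix(file_path.suffix + ".json")


def write_raw_volume(volume: CTVolume, file_path) -> None:
    """Write voxels as a headerless little-endian stream (X outermost)
    plus a JSON sidecar holding extents, spacing, dtype and sample id."""
    file_path = Path(file_path)
    data = np.ascontiguousarray(volume.voxels, dtype=np.dtype("<i2"))
    file_path.write_bytes(data.tobytes())
    meta = {
        "extents": list(volume.voxels.shape),
        "spacing": list(volume.spacing),
        "dtype": "<i2",
        "sample_id": volume.sample_id,
    }
    _sidecar_path(file_path).write_text(json.dumps(meta, indent=2))


def read_raw_volume(file_path, extents=None) -> CTVolume:
    """Read a raw voxel stream; extents come from the sidecar unless given."""
    file_path = Path(file_path)
    sidecar = _sidecar_path(file_path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if extents is None:
        if "extents" not in meta:
            raise ValueError(f"no extents given and no sidecar at {sidecar}")
        extents = tuple(meta["extents"])
    extents = tuple(int(e) for e in extents)
    dtype = np.dtype(meta.get("dtype", "<i2"))
    buf = file_path.read_bytes()
    expected = int(np.prod(extents)) * dtype.itemsize
    if len(buf) != expected:
        raise ValueError(
            f"file holds {len(buf)} bytes but extents {extents} with dtype "
            f"{dtype} require {expected}")
    voxels = np.frombuffer(buf, dtype=dtype).reshape(extents).astype(np.int64)
    spacing = tuple(meta.get("spacing", (0.25, 0.351, 0.351)))
    return CTVolume(voxels, spacing=spacing,
                    sample_id=meta.get("sample_id", file_path.stem))
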