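"""Seeded synthetic soil-core volumes with exact voxel-level labels.

Generates volumes that mimic a scanned core: a soil-matrix background at
mid-range HU, embedded low-HU pores, ellipsoidal organic blobs, high-HU
stones, and meandering burrow-like tunnels. Every voxel carries a
material label, so the exact per-slice solid/void counts of any object
class selection are known without running the imaging pipeline — the
ground truth every downstream stage is tested against.

HU jitter, when enabled, is drawn uniformly inside the material's HU
interval, which by construction lies inside its declared band(s); band
classification of a jittered volume therefore still matches the labels
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .object_classes import ObjectClassScheme, PorosityProfile, default_scheme
from .volume_io import CTVolume, HU_MAX, HU_MIN

__all__ = [
    "Material",
    "ShapeSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_volume",
    "ground_truth_profile",
    "soil_core_spec",
]


@dataclass(frozen=True)
class Material:
    """A material with an inclusive HU interval lying inside its band(s)."""

    name: str
    hu_range: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.hu_range
        if not (HU_MIN <= lo <= hi <= HU_MAX):
            raise ValueError(
                f"material {self.name!r}: HU interval [{lo},{hi}] outside "
                f"[{HU_MIN},{HU_MAX}]")

    def bands(self, scheme: ObjectClassScheme) -> frozenset[int]:
        """Set of 1-based band indices this material's interval touches."""
        lo, hi = self.hu_range
        lows = scheme.lows()
        first = int(np.searchsorted(lows, lo, side="right"))
        last = int(np.searchsorted(lows, hi, side="right"))
        return frozenset(range(first, last + 1))


@dataclass(frozen=True)
class ShapeSpec:
    """Count and size range for one shape family of one material.

    kind: 'sphere' (stones, isolated pores), 'blob' (ellipsoidal organic
    matter) or 'tunnel' (axis-meandering cylinder, e.g. earthworm burrow).
    """

    kind: str
    material: str
    count: int
    size_range: tuple[float, float]

    def __post_init__(self):
        if self.kind not in ("sphere", "blob", "tunnel"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad size range {self.size_range}")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic core; deterministic under `seed`."""

    seed: int
    extents: tuple[int, int, int]
    matrix: Material
    materials: tuple[Material, ...] = ()
    shapes: tuple[ShapeSpec, ...] = ()
    jitter: bool = True
    spacing: tuple[float, float, float] = (0.25, 0.351, 0.351)
    sample_id: str = "synthetic"

    def material_by_name(self, name: str) -> Material:
        if name == self.matrix.name:
            return self.matrix
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(f"unknown material {name!r}")

    def all_materials(self) -> list[Material]:
        return [self.matrix, *self.materials]

    # -- plain-text round trip ---------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "extents": list(self.extents),
            "jitter": self.jitter,
            "spacing": list(self.spacing),
            "sample_id": self.sample_id,
            "matrix": {"name": self.matrix.name, "hu_range": list(self.matrix.hu_range)},
            "materials": [{"name": m.name, "hu_range": list(m.hu_range)}
                          for m in self.materials],
            "shapes": [{"kind": s.kind, "material": s.material, "count": s.count,
                        "size_range": list(s.size_range)} for s in self.shapes],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            seed=int(doc["seed"]),
            extents=tuple(doc["extents"]),
            matrix=Material(doc["matrix"]["name"], tuple(doc["matrix"]["hu_range"])),
            materials=tuple(Material(m["name"], tuple(m["hu_range"]))
                            for m in doc.get("materials", [])),
            shapes=tuple(ShapeSpec(s["kind"], s["material"], int(s["count"]),
                                   tuple(s["size_range"]))
                         for s in doc.get("shapes", [])),
            jitter=bool(doc.get("jitter", True)),
            spacing=tuple(doc.get("spacing", (0.25, 0.351, 0.351))),
            sample_id=str(doc.get("sample_id", "synthetic")),
        )


@dataclass
class GroundTruth:
    """Per-voxel material ids plus the material table that decodes them."""

    labels: np.ndarray                       # (X,Y,Z) int, index into materials
    materials: tuple[Material, ...]          # id -> material
    sample_id: str = "synthetic"
    spacing: tuple[float, float, float] = (0.25, 0.351, 0.351)

    def solid_mask(self, selected_material_ids) -> np.ndarray:
        return np.isin(self.labels, sorted(selected_material_ids)).astype(np.uint8)

    def material_ids_for_classes(self, class_selection,
                                 scheme: ObjectClassScheme) -> list[int]:
        """Materials whose band set is fully inside the selected classes.

        A material partially overlapping the selection would make exact
        ground truth impossible under jitter, so that case raises.
        """
        selection = frozenset(int(c) for c in class_selection)
        ids = []
        for mid, mat in enumerate(self.materials):
            mat_bands = mat.bands(scheme)
            inter = mat_bands & selection
            if inter == mat_bands:
                ids.append(mid)
            elif inter:
                raise ValueError(
                    f"material {mat.name!r} spans bands {sorted(mat_bands)} "
                    f"which straddle the selection {sorted(selection)}")
        return ids


def _rasterize_sphere(labels, center, radius, mat_id):
    x, y, z = np.ogrid[:labels.shape[0], :labels.shape[1], :labels.shape[2]]
    d2 = ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    labels[d2 <= radius ** 2] = mat_id


def _rasterize_blob(labels, center, semiaxes, mat_id):
    x, y, z = np.ogrid[:labels.shape[0], :labels.shape[1], :labels.shape[2]]
    d = ((x - center[0]) / semiaxes[0]) ** 2 + \
        ((y - center[1]) / semiaxes[1]) ** 2 + \
        ((z - center[2]) / semiaxes[2]) ** 2
    labels[d <= 1.0] = mat_id


def _rasterize_tunnel(labels, rng, radius, mat_id):
    """Meandering cylinder along X: a random-walk center line in (Y,Z)."""
    nx, ny, nz = labels.shape
    cy, cz = rng.uniform(radius, ny - radius), rng.uniform(radius, nz - radius)
    y, z = np.ogrid[:ny, :nz]
    for ix in range(nx):
        cy = float(np.clip(cy + rng.normal(0, 0.8), radius, ny - 1 - radius))
        cz = float(np.clip(cz + rng.normal(0, 0.8), radius, nz - 1 - radius))
        disc = (y - cy) ** 2 + (z - cz) ** 2 <= radius ** 2
        labels[ix][disc] = mat_id


def generate_volume(spec: SyntheticSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterize the spec into (volume, ground truth); later shapes win.

    Deterministic: the same spec (including seed) always yields
    bit-identical voxels and labels.
    """
    rng = np.random.default_rng(spec.seed)
    materials = tuple(spec.all_materials())
    name_to_id = {m.name: i for i, m in enumerate(materials)}
    nx, ny, nz = spec.extents
    labels = np.zeros((nx, ny, nz), dtype=np.int16)  # 0 = matrix

    for shape in spec.shapes:
        mat_id = name_to_id[shape.material]
        for _ in range(shape.count):
            if shape.kind == "sphere":
                r = rng.uniform(*shape.size_range)
                center = rng.uniform((0, 0, 0), (nx, ny, nz))
                _rasterize_sphere(labels, center, r, mat_id)
            elif shape.kind == "blob":
                semiaxes = rng.uniform(shape.size_range[0], shape.size_range[1], 3)
                center = rng.uniform((0, 0, 0), (nx, ny, nz))
                _rasterize_blob(labels, center, semiaxes, mat_id)
            else:  # tunnel
                r = rng.uniform(*shape.size_range)
                _rasterize_tunnel(labels, rng, r, mat_id)

    voxels = np.empty((nx, ny, nz), dtype=np.int64)
    for mat_id, mat in enumerate(materials):
        sel = labels == mat_id
        n = int(sel.sum())
        if n == 0:
            continue
        lo, hi = mat.hu_range
        if spec.jitter and hi > lo:
            voxels[sel] = rng.integers(lo, hi + 1, size=n)
        else:
            voxels[sel] = (lo + hi) // 2

    volume = CTVolume(voxels, spacing=spec.spacing, sample_id=spec.sample_id)
    gt = GroundTruth(labels=labels, materials=materials,
                     sample_id=spec.sample_id, spacing=spec.spacing)
    return volume, gt


def ground_truth_profile(gt: GroundTruth, class_selection,
                         scheme: ObjectClassScheme | None = None) -> PorosityProfile:
    """Exact per-slice porosity from labels, no imaging pipeline involved."""
    scheme = scheme or default_scheme()
    ids = gt.material_ids_for_classes(class_selection, scheme)
    solid = gt.solid_mask(ids) if ids else np.zeros_like(gt.labels, dtype=np.uint8)
    solid_counts = solid.sum(axis=(1, 2), dtype=np.int64)
    total = gt.labels.shape[1] * gt.labels.shape[2]
    return PorosityProfile((total - solid_counts) / total,
                           object_classes=frozenset(int(c) for c in class_selection),
                           sample_id=gt.sample_id,
                           slice_thickness_mm=gt.spacing[0])


def soil_core_spec(seed: int, extents=(100, 64, 64), *, jitter: bool = True,
                   heterogeneity: float = 1.0, sample_id: str | None = None
                   ) -> SyntheticSpec:
    """Convenience spec resembling a scanned core.

    Matrix in band 3, pores and tunnels in band 1, organic blobs in
    band 2, stones in band 5. `heterogeneity` scales shape counts so
    structurally busy and quiet cores can be contrasted.
    """
    nx = extents[0]
    n = max(1, round(nx / 100 * heterogeneity))
    return SyntheticSpec(
        seed=seed,
        extents=tuple(extents),
        matrix=Material("matrix", (2300, 2800)),
        materials=(
            Material("pore", (200, 900)),
            Material("organic", (1200, 1900)),
            Material("stone", (4200, 5000)),
        ),
        shapes=(
            # pore inventory is held constant across cores so that the
            # organic/stone load (scaled by heterogeneity) dominates the
            # cross-core porosity contrast
            ShapeSpec("sphere", "pore", count=max(1, nx // 12),
                      size_range=(2.0, 5.0)),
            ShapeSpec("tunnel", "pore", count=2, size_range=(1.5, 3.0)),
            ShapeSpec("blob", "organic", count=8 * n, size_range=(2.0, 7.0)),
            ShapeSpec("sphere", "stone", count=4 * n, size_range=(2.0, 5.0)),
        ),
        jitter=jitter,
        sample_id=sample_id or f"synthetic-{seed}",
    )
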