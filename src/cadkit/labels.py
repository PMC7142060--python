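"""Voxel and 2D geometric labels — the gold-standard annotation units.

A :class:`VoxelLabel` is a sparse binary mask stored as a tight bounding
box (offset + size + mask) inside a series' voxel grid. Tightness is an
invariant: after every mutation the box is re-normalized so that every
face of the box contains at least one set voxel; a named-but-unpainted
label is legal and has size ``(0, 0, 0)``.

Painting is spacing-aware: a spherical brush sets (or clears) every voxel
whose centre lies within the brush radius in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class LabelError(ValueError):
    pass


@dataclass
class VoxelLabel:
    """Sparse binary 3D mask with an offset bounding box."""

    name: str
    offset: tuple[int, int, int] = (0, 0, 0)
    mask: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0), dtype=bool))
    attributes: dict = field(default_factory=dict)
    color: str = "#ff0000"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise LabelError("mask must be 3D")
        self.offset = tuple(int(v) for v in self.offset)

    @property
    def size(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def voxel_coords(self) -> np.ndarray:
        """Absolute (grid) coordinates of set voxels, shape (n, 3)."""
        if self.mask.size == 0:
            return np.empty((0, 3), dtype=np.int64)
        local = np.argwhere(self.mask)
        return local + np.asarray(self.offset)

    def is_empty(self) -> bool:
        return self.mask.size == 0 or not self.mask.any()

    def within(self, dims: tuple[int, int, int]) -> bool:
        if self.is_empty():
            return True
        return all(
            0 <= o and o + s <= n for o, s, n in zip(self.offset, self.size, dims)
        )

    def normalized(self) -> "VoxelLabel":
        """Tighten the bounding box; an empty label becomes size (0,0,0)."""
        if self.is_empty():
            return replace(self, offset=(0, 0, 0), mask=np.zeros((0, 0, 0), dtype=bool))
        set_idx = np.argwhere(self.mask)
        lo = set_idx.min(axis=0)
        hi = set_idx.max(axis=0) + 1
        tight = self.mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
        return replace(
            self, offset=tuple(int(o + l) for o, l in zip(self.offset, lo)), mask=tight
        )

    def copy(self) -> "VoxelLabel":
        return replace(self, mask=self.mask.copy(), attributes=dict(self.attributes))


@dataclass
class GeometricLabel:
    """2D annotation (ellipse or rectangle) on one orthogonal plane.

    Stored and round-tripped, never rasterized to voxels.
    """

    name: str
    kind: str  # ellipse | rectangle
    plane: str  # axial | sagittal | coronal
    slice_index: int
    bounds: tuple[float, float, float, float]  # (min_u, min_v, max_u, max_v) in mm
    attributes: dict = field(default_factory=dict)
    color: str = "#00ff00"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "rectangle"):
            raise LabelError(f"kind must be ellipse or rectangle, got {self.kind!r}")
        if self.plane not in ("axial", "sagittal", "coronal"):
            raise LabelError(f"unknown plane {self.plane!r}")
        u0, v0, u1, v1 = self.bounds
        if not (u1 > u0 and v1 > v0):
            raise LabelError(f"bounds must have positive extent, got {self.bounds}")


def _brush_coords(
    center: tuple[int, int, int],
    radius_mm: float,
    spacing: tuple[float, float, float],
    dims: tuple[int, int, int],
) -> np.ndarray:
    """Grid coordinates of in-bounds voxels whose centre is within the brush."""
    reach = [int(np.floor(radius_mm / s)) for s in spacing]
    ranges = [
        np.arange(max(0, c - r), min(n, c + r + 1))
        for c, r, n in zip(center, reach, dims)
    ]
    gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip((gx, gy, gz), center, spacing))
    sel = d2 <= radius_mm**2
    return np.stack([gx[sel], gy[sel], gz[sel]], axis=1)


def paint_voxels(
    label: VoxelLabel,
    center: tuple[int, int, int],
    radius_mm: float,
    mode: str,
    spacing: tuple[float, float, float],
    dims: tuple[int, int, int],
) -> VoxelLabel:
    """Apply a spherical brush; returns a new, tight label.

    ``mode`` is ``paint`` or ``erase``. The centre voxel must lie inside
    the series grid. Idempotent: painting the same brush twice equals once.
    """
    if mode not in ("paint", "erase"):
        raise LabelError(f"mode must be paint or erase, got {mode!r}")
    if not all(0 <= c < n for c, n in zip(center, dims)):
        raise LabelError(f"brush center {center} outside grid {dims}")
    coords = _brush_coords(center, radius_mm, spacing, dims)
    if coords.size == 0:
        # radius smaller than any voxel pitch still hits the centre voxel
        coords = np.array([center], dtype=np.int64)

    existing = label.voxel_coords()
    if mode == "paint":
        merged = np.unique(np.vstack([existing, coords]), axis=0)
    else:
        erase = {tuple(c) for c in coords}
        merged = np.array(
            [c for c in existing if tuple(c) not in erase], dtype=np.int64
        ).reshape(-1, 3)

    out = replace(label, offset=(0, 0, 0), mask=np.zeros((0, 0, 0), dtype=bool))
    if merged.shape[0] == 0:
        return out
    lo = merged.min(axis=0)
    hi = merged.max(axis=0) + 1
    mask = np.zeros(tuple(hi - lo), dtype=bool)
    rel = merged - lo
    mask[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    return replace(out, offset=tuple(int(v) for v in lo), mask=mask)


def label_to_volume(label: VoxelLabel, dims: tuple[int, int, int]) -> np.ndarray:
    """Full-grid uint8 0/1 volume with set voxels at offset + mask positions."""
    if not label.within(dims):
        raise LabelError(
            f"label box offset={label.offset} size={label.size} exceeds dims {dims}"
        )
    out = np.zeros(dims, dtype=np.uint8)
    if not label.is_empty():
        o = label.offset
        s = label.size
        out[o[0]:o[0] + s[0], o[1]:o[1] + s[1], o[2]:o[2] + s[2]] = label.mask
    return out


def volume_to_label(volume: np.ndarray, name: str = "label") -> VoxelLabel:
    """Inverse of :func:`label_to_volume`: tight label from a binary grid."""
    arr = np.asarray(volume) != 0
    return VoxelLabel(name=name, offset=(0, 0, 0), mask=arr).normalized()


# --- run-length encoding for compact JSON storage ---------------------

def mask_to_rle(mask: np.ndarray) -> list[int]:
    """Run lengths of the C-order flattened mask, starting with a 0-run
    (possibly of length 0)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    lengths = np.diff(np.concatenate([[0], changes + 1, [flat.size]]))
    runs = lengths.tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_to_mask(runs: list[int], size: tuple[int, int, int]) -> np.ndarray:
    total = int(np.prod(size))
    flat = np.zeros(total, dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    if pos != total:
        raise LabelError(f"run lengths sum to {pos}, expected {total}")
    return flat.reshape(size)
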