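"""Multiplanar reconstruction (MPR): deterministic section extraction.

One reconstruction kernel serves every consumer — orthogonal grid planes
are exact array copies (lossless), oblique planes are resampled with
nearest-neighbour or trilinear interpolation, and a window/level transform
maps stored values to 8-bit display gray.

Sampling conventions (stated because half-pixel conventions are the classic
source of off-by-half bugs):

* output pixel ``(i, j)`` samples patient space at exactly
  ``origin + i*u_axis + j*v_axis`` (sample-at-corner, no centre offset);
* in trilinear mode a sample exactly on a voxel boundary uses the
  mathematical weights — a zero-weight neighbour contributes nothing even
  when it lies outside the volume, so values do not bleed at exact edges;
* samples with any nonzero-weight neighbour outside the grid yield
  ``fill_value`` (defaulting to the volume minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

AXES = ("axial", "sagittal", "coronal")
_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


class SectionError(ValueError):
    pass


@dataclass
class SectionSpec:
    """An oblique section: plane origin, pixel-step axes and output size.

    ``u_axis``/``v_axis`` are patient-space mm vectors spanning one output
    pixel step in section-x and section-y respectively; their length sets
    the output pixel pitch.
    """

    origin: tuple[float, float, float]
    u_axis: tuple[float, float, float]
    v_axis: tuple[float, float, float]
    out_size: tuple[int, int]
    interpolation: str = "trilinear"
    fill_value: float | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.u_axis, dtype=float)
        v = np.asarray(self.v_axis, dtype=float)
        if np.linalg.norm(np.cross(u, v)) <= 1e-9:
            raise SectionError("u_axis and v_axis must be nonzero and not parallel")
        if any(n < 1 for n in self.out_size):
            raise SectionError(f"out_size must be positive, got {self.out_size}")
        if self.interpolation not in ("nearest", "trilinear"):
            raise SectionError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class WindowSpec:
    """Window/level display transform: centre ``level``, range ``width``."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SectionError(f"window width must be > 0, got {self.width}")


def orthogonal_section(volume: Volume, axis: str, index: int) -> np.ndarray:
    """Exact copy of a stored grid plane — no interpolation.

    Returned with shape (n_fast, n_slow) matching the in-plane axes in
    (x, y, z) order: axial -> (nx, ny), sagittal -> (ny, nz),
    coronal -> (nx, nz).
    """
    if axis not in _AXIS_INDEX:
        raise SectionError(f"axis must be one of {AXES}, got {axis!r}")
    ax = _AXIS_INDEX[axis]
    n = volume.dims[ax]
    if not (0 <= index < n):
        raise SectionError(f"index {index} out of range [0, {n}) for {axis} axis")
    if axis == "axial":
        return volume.data[:, :, index].copy()
    if axis == "sagittal":
        return volume.data[index, :, :].copy()
    return volume.data[:, index, :].copy()


def _sample(volume: Volume, points_mm: np.ndarray, interpolation: str, fill: float) -> np.ndarray:
    """Sample the volume at an (..., 3) array of patient-space points."""
    idx = volume.mm_to_voxel(points_mm)  # continuous voxel coords, (..., 3)
    dims = np.asarray(volume.dims)
    data = volume.data.astype(np.float64)

    if interpolation == "nearest":
        nearest = np.rint(idx).astype(np.int64)
        inside = np.all((nearest >= 0) & (nearest < dims), axis=-1)
        clamped = np.clip(nearest, 0, dims - 1)
        out = data[clamped[..., 0], clamped[..., 1], clamped[..., 2]]
        out[~inside] = fill
        return out

    base = np.floor(idx).astype(np.int64)
    frac = idx - base
    out = np.zeros(idx.shape[:-1], dtype=np.float64)
    valid = np.ones(idx.shape[:-1], dtype=bool)
    for corner in range(8):
        offs = np.array([(corner >> a) & 1 for a in range(3)])
        nbr = base + offs
        w = np.ones(idx.shape[:-1], dtype=np.float64)
        for a in range(3):
            w *= frac[..., a] if offs[a] else 1.0 - frac[..., a]
        inb = np.all((nbr >= 0) & (nbr < dims), axis=-1)
        # a zero-weight out-of-bounds neighbour is harmless by convention
        valid &= inb | (w == 0.0)
        clamped = np.clip(nbr, 0, dims - 1)
        out += w * data[clamped[..., 0], clamped[..., 1], clamped[..., 2]]
    out[~valid] = fill
    return out


def oblique_section(volume: Volume, spec: SectionSpec) -> np.ndarray:
    """Resample an arbitrary plane: ``output[j, i]`` is the volume sampled
    at ``origin + i*u_axis + j*v_axis``.

    Fully deterministic; out-of-volume samples yield the spec's fill value
    (volume minimum when unset). Output shape is ``(h, w)``.
    """
    w, h = spec.out_size
    fill = float(volume.data.min()) if spec.fill_value is None else float(spec.fill_value)
    ii, jj = np.meshgrid(np.arange(w), np.arange(h))  # shapes (h, w)
    points = (
        np.asarray(spec.origin, dtype=float)
        + ii[..., None] * np.asarray(spec.u_axis, dtype=float)
        + jj[..., None] * np.asarray(spec.v_axis, dtype=float)
    )
    return _sample(volume, points, spec.interpolation, fill)


def apply_window(image: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Map stored values to 8-bit gray:
    ``round(clamp((v - (level - width/2)) / width, 0, 1) * 255)``,
    round-half-up. Monotone non-decreasing in the input."""
    v = np.asarray(image, dtype=np.float64)
    t = np.clip((v - (window.level - window.width / 2.0)) / window.width, 0.0, 1.0)
    return np.floor(t * 255.0 + 0.5).astype(np.uint8)


def section_to_png(image: np.ndarray, window: WindowSpec, path) -> None:
    """Export a windowed section as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(apply_window(image, window), mode="L").save(path, format="PNG")
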