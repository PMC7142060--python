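"""3D image volume with patient-space geometry.

A :class:`Volume` is the unit consumed by the reconstruction engine and by
CAD plugins: a scalar grid indexed ``data[x, y, z]`` together with the
geometry needed to place each voxel in patient space (spacing in mm, the
patient-space origin of voxel ``(0, 0, 0)``, and the row/column direction
cosines of the acquisition, from which the slice normal is derived).

Conventions
-----------
* Voxel indices are 0-based; ``data.shape == (nx, ny, nz)``.
* Patient coordinates follow the DICOM LPS convention.
* Voxel index ``(i, j, k)`` maps to
  ``origin + i*sx*row + j*sy*col + k*sz*normal`` — i.e. voxel (0,0,0)
  sits exactly at ``origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: element types supported by the volume contract
SUPPORTED_DTYPES = (np.dtype("int16"), np.dtype("uint16"), np.dtype("uint8"))

_ORTHO_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when a volume's geometry fields are inconsistent."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing, origin and orientation.

    Parameters
    ----------
    data
        Scalar array of shape ``(nx, ny, nz)``; dtype must be one of
        int16, uint16, uint8.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        Patient-space position (mm, LPS) of voxel ``(0, 0, 0)``.
    row_cosine, col_cosine
        Unit direction cosines of the image rows and columns
        (the two halves of the DICOM ImageOrientationPatient attribute).
    rescale
        ``(slope, intercept)`` already applied to ``data`` at load time;
        kept for provenance only.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    row_cosine: tuple[float, float, float] = (1.0, 0.0, 0.0)
    col_cosine: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rescale: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"data must be 3D, got {self.data.ndim}D")
        if self.data.dtype not in SUPPORTED_DTYPES:
            raise GeometryError(
                f"unsupported value_type {self.data.dtype}; "
                f"supported: {[str(d) for d in SUPPORTED_DTYPES]}"
            )
        if any(n < 1 for n in self.data.shape):
            raise GeometryError(f"dims must be positive, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(v) for v in self.origin)
        r = np.asarray(self.row_cosine, dtype=float)
        c = np.asarray(self.col_cosine, dtype=float)
        if abs(np.linalg.norm(r) - 1.0) > _ORTHO_TOL or abs(np.linalg.norm(c) - 1.0) > _ORTHO_TOL:
            raise GeometryError("direction cosines must be unit length")
        if abs(float(np.dot(r, c))) > _ORTHO_TOL:
            raise GeometryError("row/column direction cosines must be orthogonal")
        self.row_cosine = tuple(float(v) for v in r)
        self.col_cosine = tuple(float(v) for v in c)
        self.rescale = (float(self.rescale[0]), float(self.rescale[1]))

    # -- geometry -----------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        """Grid size ``(nx, ny, nz)``."""
        return self.data.shape  # type: ignore[return-value]

    @property
    def value_type(self) -> str:
        return str(self.data.dtype)

    @property
    def slice_normal(self) -> tuple[float, float, float]:
        """Unit normal of the slice plane (row x col)."""
        n = np.cross(self.row_cosine, self.col_cosine)
        return tuple(float(v) for v in n)

    @property
    def direction_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are row, column and normal cosines."""
        return np.column_stack([self.row_cosine, self.col_cosine, self.slice_normal])

    def voxel_to_mm(self, index) -> np.ndarray:
        """Map (continuous) voxel indices to patient-space mm.

        Accepts a single triple or an ``(..., 3)`` array.
        """
        idx = np.asarray(index, dtype=float)
        stepped = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + stepped @ self.direction_matrix.T

    def mm_to_voxel(self, point) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm`: mm point to continuous voxel index."""
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        local = p @ self.direction_matrix  # orthonormal: transpose == inverse
        return local / np.asarray(self.spacing)

    def copy(self) -> "Volume":
        return Volume(
            data=self.data.copy(),
            spacing=self.spacing,
            origin=self.origin,
            row_cosine=self.row_cosine,
            col_cosine=self.col_cosine,
            rescale=self.rescale,
        )
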