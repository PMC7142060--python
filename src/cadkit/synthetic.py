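"""Synthetic DICOM series generator with planted lesions.

Produces one-file-per-slice DICOM series with fully known geometry and
ground truth: a Gaussian-noise background with spherical lesions of stated
intensity planted at known voxel centres. A fixed seed yields byte-identical
payloads, so fixtures never need to be stored — they are regenerated.

The generated series carry fake identity attributes (patient name, ID,
birth date, institution...) precisely so that the anonymization and
sandbox contracts have something real to strip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import Volume

_UID_ROOT = "1.2.826.0.1.3680043.8.498"  # pydicom's public test root


class SyntheticSpecError(ValueError):
    """Invalid synthetic-series specification."""


@dataclass
class Lesion:
    """A spherical lesion: centre voxel, radius in mm, stored intensity."""

    center: tuple[int, int, int]
    radius_mm: float
    intensity: int


@dataclass
class SyntheticSpec:
    """Specification of a synthetic DICOM series.

    Defaults emulate a thin-slice MR-angiography head study
    (632x768 in-plane, 128 slices) scaled to whatever ``dims`` is given.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_level: int = 100
    noise_sd: float = 0.0
    lesions: list[Lesion] = field(default_factory=list)
    seed: int = 0
    modality: str = "MR"
    patient_name: str = "Synthetic^Subject"
    patient_id: str = "SYN0001"

    def __post_init__(self) -> None:
        self.lesions = [
            l if isinstance(l, Lesion) else Lesion(tuple(l[0]), float(l[1]), int(l[2]))
            for l in self.lesions
        ]
        if any(n < 1 for n in self.dims):
            raise SyntheticSpecError(f"dims must be positive, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise SyntheticSpecError(f"spacing must be positive, got {self.spacing}")
        for lesion in self.lesions:
            if lesion.radius_mm <= 0:
                raise SyntheticSpecError(f"lesion radius must be > 0, got {lesion.radius_mm}")
            if not all(0 <= c < n for c, n in zip(lesion.center, self.dims)):
                raise SyntheticSpecError(
                    f"lesion center {lesion.center} outside grid {self.dims}"
                )

    @property
    def series_uid(self) -> str:
        return f"{_UID_ROOT}.1.{self.seed}"


def sphere_mask(
    dims: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within ``radius_mm`` (mm)
    of the centre voxel, spacing-aware."""
    idx = np.indices(dims, dtype=np.float64)
    d2 = sum(
        ((idx[a] - center[a]) * spacing[a]) ** 2 for a in range(3)
    )
    return d2 <= radius_mm**2


def generate_volume(spec: SyntheticSpec) -> np.ndarray:
    """The generator's internal ground-truth array, shape (nx, ny, nz), int16."""
    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.dims, spec.background_level, dtype=np.float64)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=spec.dims)
    for lesion in spec.lesions:
        mask = sphere_mask(spec.dims, spec.spacing, lesion.center, lesion.radius_mm)
        data[mask] = lesion.intensity
    return np.clip(np.rint(data), -32768, 32767).astype(np.int16)


def generate_synthetic_series(spec: SyntheticSpec) -> list[bytes]:
    """Render the spec as per-slice DICOM Part-10 payloads (slice order).

    Deterministic: the same spec and seed produce byte-identical payloads.
    The seed is recorded in SeriesDescription for provenance.
    """
    data = generate_volume(spec)
    nx, ny, nz = spec.dims
    sx, sy, sz = spec.spacing
    payloads: list[bytes] = []
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
        ds.SOPInstanceUID = f"{_UID_ROOT}.2.{spec.seed}.{k + 1}"
        ds.StudyInstanceUID = f"{_UID_ROOT}.0.{spec.seed}"
        ds.SeriesInstanceUID = spec.series_uid
        ds.Modality = spec.modality
        ds.SeriesDescription = f"synthetic seed={spec.seed}"
        ds.Manufacturer = "cadkit synthetic"
        ds.PatientName = spec.patient_name
        ds.PatientID = spec.patient_id
        ds.PatientBirthDate = "19700101"
        ds.PatientAddress = "1 Synthetic Way"
        ds.ReferringPhysicianName = "Synthetic^Physician"
        ds.InstitutionName = "Synthetic Hospital"
        ds.AccessionNumber = f"ACC{spec.seed:06d}"
        ds.StudyDate = "20200101"
        ds.ContentDate = "20200101"
        ds.StudyTime = "000000"
        ds.ContentTime = "000000"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * sz]
        ds.SliceThickness = sz
        ds.PixelSpacing = [sy, sx]  # (row spacing, column spacing)
        ds.Rows = ny
        ds.Columns = nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        buf = io.BytesIO()
        pydicom.dcmwrite(buf, ds, enforce_file_format=True)
        payloads.append(buf.getvalue())
    return payloads


def spec_volume(spec: SyntheticSpec) -> Volume:
    """Ground-truth Volume for a spec, bypassing the DICOM round trip."""
    return Volume(data=generate_volume(spec), spacing=spec.spacing)
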