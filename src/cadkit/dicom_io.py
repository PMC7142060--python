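"""DICOM series ingestion and metadata anonymization.

Reads classic one-file-per-slice DICOM series (monochrome, uncompressed)
into a geometry-complete :class:`~cadkit.volume.Volume` plus a
:class:`SeriesMetadata` record of selected header values, and strips
protected health information (PHI) from that record.

Slice ordering is geometry-authoritative: slices are sorted by the
projection of ImagePositionPatient onto the slice normal, with
InstanceNumber only as a tie-break. Non-uniform slice spacing is rejected
rather than resampled — the plugin contract assumes a regular grid.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pydicom

from .volume import Volume

#: relative tolerance on slice-gap uniformity
SLICE_GAP_RTOL = 1e-3

#: header keywords extracted into SeriesMetadata when present
DEFAULT_SELECTED_TAGS = (
    "Modality",
    "SeriesInstanceUID",
    "SeriesDescription",
    "Manufacturer",
    "ManufacturerModelName",
    "Rows",
    "Columns",
    "PixelSpacing",
    "SliceThickness",
    "SpacingBetweenSlices",
    "KVP",
    "RepetitionTime",
    "EchoTime",
    "MagneticFieldStrength",
    "RescaleSlope",
    "RescaleIntercept",
    # identity attributes: present until anonymize() removes them
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientAddress",
    "ReferringPhysicianName",
    "InstitutionName",
    "AccessionNumber",
    "StationName",
)


class DicomSeriesError(ValueError):
    """A set of files does not form one loadable series."""


@dataclass
class SeriesMetadata:
    """Selected header values for one DICOM series.

    ``key_values`` is an ordered list of ``(keyword, string value)`` pairs;
    ``phi_removed`` records whether :func:`anonymize` has been applied.
    """

    series_uid: str
    modality: str
    key_values: list[tuple[str, str]] = field(default_factory=list)
    phi_removed: bool = False

    def get(self, keyword: str) -> str | None:
        for k, v in self.key_values:
            if k == keyword:
                return v
        return None

    def keywords(self) -> list[str]:
        return [k for k, _ in self.key_values]


def load_phi_tags(path: str | os.PathLike | None = None) -> frozenset[str]:
    """Load the PHI keyword list: one keyword per line, ``#`` comments.

    With no path, the default list shipped with the package is used.
    """
    if path is None:
        text = resources.files("cadkit").joinpath("data/phi_tags.txt").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    tags = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            tags.add(line)
    return frozenset(tags)


DEFAULT_PHI_TAGS = load_phi_tags()


def _is_private_keyword(keyword: str) -> bool:
    # private attributes carry no public keyword; they surface as "(gggg,eeee)"
    if keyword.startswith("(") and keyword.endswith(")") and "," in keyword:
        group = keyword[1:].split(",")[0]
        try:
            return int(group, 16) % 2 == 1
        except ValueError:
            return False
    return False


def anonymize(
    meta: SeriesMetadata, phi_tags: frozenset[str] | None = None
) -> SeriesMetadata:
    """Return a copy of ``meta`` with every PHI keyword removed.

    Non-PHI pairs are preserved verbatim and in order; missing PHI tags are
    a no-op, so the operation is idempotent. Private tags are always
    removed.
    """
    phi = DEFAULT_PHI_TAGS if phi_tags is None else phi_tags
    kept = [
        (k, v)
        for k, v in meta.key_values
        if k not in phi and not _is_private_keyword(k)
    ]
    return replace(meta, key_values=kept, phi_removed=True)


def _read_dataset(f) -> pydicom.Dataset:
    if isinstance(f, (bytes, bytearray)):
        return pydicom.dcmread(io.BytesIO(f))
    return pydicom.dcmread(f)


def _extract_metadata(ds: pydicom.Dataset, selected) -> SeriesMetadata:
    kv: list[tuple[str, str]] = []
    for keyword in selected:
        if keyword in ds:
            value = ds[keyword].value
            if isinstance(value, (list, pydicom.multival.MultiValue)):
                kv.append((keyword, "\\".join(str(v) for v in value)))
            else:
                kv.append((keyword, str(value)))
    # surface private tags so the anonymizer can strip them
    for elem in ds:
        if elem.tag.is_private and elem.VR not in ("OB", "OW", "SQ"):
            kv.append((f"({elem.tag.group:04x},{elem.tag.element:04x})", str(elem.value)))
    return SeriesMetadata(
        series_uid=str(ds.SeriesInstanceUID),
        modality=str(getattr(ds, "Modality", "")),
        key_values=kv,
    )


def load_dicom_series(
    files, selected_tags=DEFAULT_SELECTED_TAGS
) -> tuple[Volume, SeriesMetadata]:
    """Load per-slice DICOM payloads (paths, file objects or bytes) into a
    Volume plus SeriesMetadata.

    The files must share one SeriesInstanceUID, one in-plane size and one
    pixel spacing. Slices are ordered by position along the slice normal;
    the slice spacing is derived from adjacent position differences and
    must be uniform to within ``SLICE_GAP_RTOL`` relative tolerance.
    """
    datasets = [_read_dataset(f) for f in files]
    if not datasets:
        raise DicomSeriesError("empty series: at least one file required")

    uids = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(uids) > 1:
        raise DicomSeriesError(f"mixed series UIDs: {sorted(uids)}")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise DicomSeriesError(f"non-uniform in-plane size: {sorted(shapes)}")
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) > 1:
        raise DicomSeriesError(f"non-uniform pixel spacing: {sorted(spacings)}")

    ds0 = datasets[0]
    iop = [float(v) for v in getattr(ds0, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    row_cosine = np.array(iop[:3])
    col_cosine = np.array(iop[3:])
    normal = np.cross(row_cosine, col_cosine)

    def position(ds) -> np.ndarray:
        return np.array([float(v) for v in getattr(ds, "ImagePositionPatient", [0, 0, 0])])

    datasets.sort(
        key=lambda ds: (float(np.dot(position(ds), normal)), int(getattr(ds, "InstanceNumber", 0)))
    )

    nz = len(datasets)
    # PixelSpacing is (row spacing, column spacing) = (sy, sx)
    sy, sx = next(iter(spacings))
    if nz == 1:
        sz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    else:
        proj = [float(np.dot(position(ds), normal)) for ds in datasets]
        gaps = np.diff(proj)
        sz = float(np.mean(gaps))
        if sz <= 0:
            raise DicomSeriesError("slices share a position; cannot derive slice spacing")
        for i, g in enumerate(gaps):
            if abs(g - sz) > SLICE_GAP_RTOL * abs(sz):
                raise DicomSeriesError(
                    f"non-uniform slice spacing: gap between slices {i} and {i + 1} "
                    f"is {g:.6g} mm vs mean {sz:.6g} mm"
                )

    ny, nx = next(iter(shapes))
    slope = float(getattr(ds0, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds0, "RescaleIntercept", 0.0) or 0.0)

    first = datasets[0].pixel_array
    out_dtype = np.dtype("int16") if (intercept < 0 or first.dtype == np.int16) else first.dtype
    if out_dtype not in (np.dtype("int16"), np.dtype("uint16"), np.dtype("uint8")):
        out_dtype = np.dtype("int16")
    data = np.empty((nx, ny, nz), dtype=out_dtype)
    for k, ds in enumerate(datasets):
        plane = ds.pixel_array.astype(np.float64) * slope + intercept
        data[:, :, k] = np.rint(plane).astype(out_dtype).T  # pixel_array is (rows, cols)

    origin = tuple(position(datasets[0]))
    volume = Volume(
        data=data,
        spacing=(float(sx), float(sy), sz),
        origin=origin,
        row_cosine=tuple(row_cosine),
        col_cosine=tuple(col_cosine),
        rescale=(slope, intercept),
    )
    meta = _extract_metadata(ds0, selected_tags)
    return volume, meta
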