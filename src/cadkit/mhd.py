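"""ITK MetaImage (.mhd + .raw) reader/writer.

The interchange format for volumes: an ASCII metaheader naming a raw voxel
buffer. Only a deliberately narrow dialect is supported so that plugins get
a bit-exact, dependency-free contract:

* uncompressed, local raw file (no embedded data, no file lists),
* little-endian byte order,
* element types MET_SHORT / MET_USHORT / MET_UCHAR,
* raw buffer in x-fastest order.

Anything outside this dialect is an explicit :class:`MhdDialectError`,
never a silent best-effort read.
"""

from __future__ import annotations

import os

import numpy as np

from .volume import Volume

_TYPE_TO_MET = {
    np.dtype("int16"): "MET_SHORT",
    np.dtype("uint16"): "MET_USHORT",
    np.dtype("uint8"): "MET_UCHAR",
}
_MET_TO_TYPE = {v: k for k, v in _TYPE_TO_MET.items()}


class MhdError(ValueError):
    """Malformed or inconsistent MetaImage pair."""


class MhdDialectError(MhdError):
    """Header valid MetaImage but outside the supported dialect."""


def write_mhd(volume: Volume, path: str | os.PathLike) -> tuple[str, str]:
    """Write ``<path>.mhd`` + ``<path>.raw`` (path may include ``.mhd``).

    Returns the (header, raw) paths written. The raw buffer is the volume's
    array serialised x-fastest, little-endian.
    """
    path = os.fspath(path)
    if path.endswith(".mhd"):
        path = path[:-4]
    dtype = volume.data.dtype
    if dtype not in _TYPE_TO_MET:
        raise MhdError(f"unsupported value_type {dtype}")
    header_path = path + ".mhd"
    raw_path = path + ".raw"
    raw_name = os.path.basename(raw_path)
    d = volume.direction_matrix
    # TransformMatrix rows are the x/y/z index direction cosines
    tm = " ".join(f"{v:.10g}" for v in d.T.ravel())
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        f"TransformMatrix = {tm}",
        "Offset = " + " ".join(f"{v:.10g}" for v in volume.origin),
        "CenterOfRotation = 0 0 0",
        "ElementSpacing = " + " ".join(f"{v:.10g}" for v in volume.spacing),
        "DimSize = " + " ".join(str(n) for n in volume.dims),
        f"ElementType = {_TYPE_TO_MET[dtype]}",
        f"ElementDataFile = {raw_name}",
    ]
    with open(header_path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")
    # x-fastest order == Fortran order for (x, y, z)-indexed arrays
    buf = np.ascontiguousarray(volume.data.astype(dtype.newbyteorder("<"))).tobytes(order="F")
    with open(raw_path, "wb") as fh:
        fh.write(buf)
    return header_path, raw_path


def _parse_header(header_path: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    with open(header_path, "r", encoding="ascii") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" not in line:
                raise MhdError(f"malformed header line: {line!r}")
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    return fields


def read_mhd(path: str | os.PathLike) -> Volume:
    """Read a MetaImage pair written in the supported dialect.

    Raises :class:`MhdError` on a missing raw file or a DimSize/byte-length
    mismatch (the error states both numbers), :class:`MhdDialectError` on
    compressed data, non-local data files, big-endian buffers or unsupported
    element types.
    """
    header_path = os.fspath(path)
    fields = _parse_header(header_path)

    if fields.get("NDims", "3") != "3":
        raise MhdDialectError(f"unsupported dialect: NDims = {fields.get('NDims')}")
    if fields.get("CompressedData", "False").lower() == "true":
        raise MhdDialectError("unsupported dialect: CompressedData = True")
    if fields.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise MhdDialectError("unsupported dialect: big-endian buffers not supported")
    elem_type = fields.get("ElementType")
    if elem_type not in _MET_TO_TYPE:
        raise MhdDialectError(f"unsupported dialect: ElementType = {elem_type}")
    data_file = fields.get("ElementDataFile")
    if not data_file or data_file.upper() in ("LIST", "LOCAL") or os.path.isabs(data_file):
        raise MhdDialectError(f"unsupported dialect: ElementDataFile = {data_file}")

    try:
        dims = tuple(int(v) for v in fields["DimSize"].split())
        spacing = tuple(float(v) for v in fields.get("ElementSpacing", "1 1 1").split())
        origin = tuple(float(v) for v in fields.get("Offset", "0 0 0").split())
    except (KeyError, ValueError) as exc:
        raise MhdError(f"malformed header field: {exc}") from exc
    if len(dims) != 3:
        raise MhdError(f"DimSize must have 3 components, got {fields['DimSize']!r}")

    tm = fields.get("TransformMatrix", "1 0 0 0 1 0 0 0 1")
    m = np.array([float(v) for v in tm.split()], dtype=float).reshape(3, 3)
    row_cosine, col_cosine = m[0], m[1]

    raw_path = os.path.join(os.path.dirname(header_path), data_file)
    if not os.path.exists(raw_path):
        raise MhdError(f"raw file not found: {raw_path}")
    dtype = _MET_TO_TYPE[elem_type]
    expected = int(np.prod(dims)) * dtype.itemsize
    actual = os.path.getsize(raw_path)
    if actual != expected:
        raise MhdError(
            f"DimSize {dims} implies {expected} bytes but raw file has {actual} bytes"
        )
    with open(raw_path, "rb") as fh:
        buf = fh.read()
    arr = np.frombuffer(buf, dtype=dtype.newbyteorder("<")).astype(dtype)
    data = arr.reshape(dims, order="F")
    return Volume(
        data=data,
        spacing=spacing,  # type: ignore[arg-type]
        origin=origin,  # type: ignore[arg-type]
        row_cosine=tuple(row_cosine),
        col_cosine=tuple(col_cosine),
    )
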