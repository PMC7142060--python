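"""Clinical-case data model: projects, cases, revisions, integrity.

Cases are the organizing unit of the image database. Each case belongs to
a project (which fixes the attribute schemas), references one or more
image series by UID plus a content fingerprint, and carries an append-only
list of revisions — immutable snapshots of attributes and labels at a time
point. Series can never be removed from a case; if a series' pixel content
or image count changes after registration, an integrity check flags it.

A case can be exported as a self-contained archive (anonymized metadata,
MHD/raw volume and label files, one JSON document) and re-imported
losslessly for everything that is not PHI.
"""

from __future__ import annotations

import hashlib
import json
import os
import secrets
import time
from dataclasses import dataclass, field

import numpy as np

from . import schema as schema_mod
from .dicom_io import SeriesMetadata, anonymize
from .labels import (
    GeometricLabel,
    LabelError,
    VoxelLabel,
    label_to_volume,
    mask_to_rle,
    rle_to_mask,
    volume_to_label,
)
from .mhd import read_mhd, write_mhd
from .volume import Volume


class CaseError(ValueError):
    pass


class ValidationFailure(CaseError):
    """Attribute document rejected; carries the itemized violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations))


@dataclass
class Project:
    """A group of cases sharing attribute schemas."""

    project_id: str
    name: str
    case_attribute_schema: dict = field(default_factory=dict)
    label_attribute_schema: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        schema_mod.check_schema(self.case_attribute_schema)
        schema_mod.check_schema(self.label_attribute_schema)


@dataclass(frozen=True)
class SeriesRef:
    series_uid: str
    fingerprint: str
    dims: tuple[int, int, int]


@dataclass(frozen=True)
class Revision:
    """Immutable snapshot: attributes + per-series labels at a time point."""

    creator: str
    timestamp: float
    description: str
    case_attributes: dict
    series_labels: dict  # series_uid -> tuple of labels (voxel or geometric)


@dataclass
class ClinicalCase:
    case_id: str
    project_id: str
    domain: str
    series_refs: list[SeriesRef]
    revisions: list[Revision]


def new_case_id() -> str:
    """Random 160-bit hex string; collisions are negligible at any
    realistic store size."""
    return secrets.token_hex(20)


def content_fingerprint(volume: Volume) -> str:
    """SHA-256 over the image count and the per-slice pixel buffers in
    slice order — changes iff pixel content or slice count changes."""
    h = hashlib.sha256()
    nz = volume.dims[2]
    h.update(str(nz).encode())
    for k in range(nz):
        h.update(np.ascontiguousarray(volume.data[:, :, k]).tobytes())
    return h.hexdigest()


def create_case(
    project: Project,
    series: list[tuple[SeriesMetadata, Volume]],
    domain: str,
    creator: str = "system",
) -> ClinicalCase:
    """Create a case over ≥1 series with a fresh globally unique id and
    one initial empty revision."""
    if not series:
        raise CaseError("a case requires at least one series")
    refs = [
        SeriesRef(meta.series_uid, content_fingerprint(vol), vol.dims)
        for meta, vol in series
    ]
    initial = Revision(
        creator=creator,
        timestamp=time.time(),
        description="case created",
        case_attributes={},
        series_labels={r.series_uid: () for r in refs},
    )
    return ClinicalCase(
        case_id=new_case_id(),
        project_id=project.project_id,
        domain=domain,
        series_refs=refs,
        revisions=[initial],
    )


def _validate_labels(labels_by_series, case: ClinicalCase, project: Project):
    known = {r.series_uid: r.dims for r in case.series_refs}
    violations: list[schema_mod.Violation] = []
    for uid, labels in labels_by_series.items():
        if uid not in known:
            raise CaseError(
                f"series {uid} is not part of this case; the series list "
                "of a case cannot be changed"
            )
        for label in labels:
            violations.extend(
                schema_mod.Violation(f"{uid}/{label.name}/{v.field}", v.message)
                for v in schema_mod.validate_attributes(
                    label.attributes, project.label_attribute_schema
                )
            )
            if isinstance(label, VoxelLabel) and not label.within(known[uid]):
                raise CaseError(
                    f"label {label.name!r} exceeds series {uid} dims {known[uid]}"
                )
    return violations


def add_revision(
    case: ClinicalCase,
    project: Project,
    attributes: dict,
    labels_by_series: dict | None,
    creator: str,
    description: str = "",
) -> ClinicalCase:
    """Append a new revision; every prior revision is untouched.

    Attributes must validate against the project's case schema and each
    label's attributes against the label schema; any violation leaves the
    case unchanged and raises :class:`ValidationFailure` listing every
    failing field. The series list can never shrink.
    """
    labels_by_series = dict(labels_by_series or {})
    violations = list(
        schema_mod.validate_attributes(attributes, project.case_attribute_schema)
    )
    violations.extend(_validate_labels(labels_by_series, case, project))
    if violations:
        raise ValidationFailure(violations)

    frozen_labels = {
        r.series_uid: tuple(
            l.copy() if isinstance(l, VoxelLabel) else l
            for l in labels_by_series.get(r.series_uid, ())
        )
        for r in case.series_refs
    }
    last_ts = case.revisions[-1].timestamp if case.revisions else 0.0
    rev = Revision(
        creator=creator,
        timestamp=max(time.time(), last_ts),  # clock never runs backwards here
        description=description,
        case_attributes=dict(attributes),
        series_labels=frozen_labels,
    )
    case.revisions.append(rev)
    return case


@dataclass(frozen=True)
class IntegrityWarning:
    series_uid: str
    reason: str  # "content changed" | "missing series"

    def __str__(self) -> str:
        return f"series {self.series_uid}: {self.reason}"


def series_integrity_check(
    case: ClinicalCase, current: dict[str, Volume]
) -> list[IntegrityWarning]:
    """Warn iff any series' current fingerprint differs from the one
    stored at case creation; a missing series is a distinct warning."""
    warnings = []
    for ref in case.series_refs:
        vol = current.get(ref.series_uid)
        if vol is None:
            warnings.append(IntegrityWarning(ref.series_uid, "missing series"))
        elif content_fingerprint(vol) != ref.fingerprint:
            warnings.append(IntegrityWarning(ref.series_uid, "content changed"))
    return warnings


# --- export / import --------------------------------------------------

def _label_to_json(label) -> dict:
    if isinstance(label, VoxelLabel):
        return {
            "variant": "voxel",
            "name": label.name,
            "offset": list(label.offset),
            "size": list(label.size),
            "rle": mask_to_rle(label.mask),
            "attributes": label.attributes,
            "color": label.color,
            "alpha": label.alpha,
        }
    return {
        "variant": "geometric",
        "name": label.name,
        "kind": label.kind,
        "plane": label.plane,
        "slice_index": label.slice_index,
        "bounds": list(label.bounds),
        "attributes": label.attributes,
        "color": label.color,
        "alpha": label.alpha,
    }


def _label_from_json(doc: dict):
    if doc["variant"] == "voxel":
        return VoxelLabel(
            name=doc["name"],
            offset=tuple(doc["offset"]),
            mask=rle_to_mask(doc["rle"], tuple(doc["size"])),
            attributes=doc["attributes"],
            color=doc["color"],
            alpha=doc["alpha"],
        )
    return GeometricLabel(
        name=doc["name"],
        kind=doc["kind"],
        plane=doc["plane"],
        slice_index=doc["slice_index"],
        bounds=tuple(doc["bounds"]),
        attributes=doc["attributes"],
        color=doc["color"],
        alpha=doc["alpha"],
    )


def export_case(
    case: ClinicalCase,
    series: dict[str, tuple[SeriesMetadata, Volume]],
    dest: str | os.PathLike,
    phi_tags=None,
) -> str:
    """Write a self-contained case archive directory.

    Layout: ``case.json`` plus, per series, anonymized ``metadata.json``,
    ``volume.mhd|.raw`` and — for the labels of the latest revision —
    ``labels/<name>.mhd|.raw`` as uint8 0/1 volumes. All revisions
    (labels run-length-encoded) live in ``case.json`` so the archive is
    lossless for everything but PHI.
    """
    dest = os.fspath(dest)
    os.makedirs(dest, exist_ok=True)
    doc = {
        "format": "cadkit-case-archive",
        "version": 1,
        "case_id": case.case_id,
        "project_id": case.project_id,
        "domain": case.domain,
        "series": [
            {"series_uid": r.series_uid, "fingerprint": r.fingerprint, "dims": list(r.dims)}
            for r in case.series_refs
        ],
        "revisions": [
            {
                "creator": rev.creator,
                "timestamp": rev.timestamp,
                "description": rev.description,
                "case_attributes": rev.case_attributes,
                "series_labels": {
                    uid: [_label_to_json(l) for l in labels]
                    for uid, labels in rev.series_labels.items()
                },
            }
            for rev in case.revisions
        ],
    }
    with open(os.path.join(dest, "case.json"), "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)

    latest = case.revisions[-1]
    for ref in case.series_refs:
        meta, vol = series[ref.series_uid]
        sdir = os.path.join(dest, "series", ref.series_uid)
        os.makedirs(sdir, exist_ok=True)
        anon = anonymize(meta, phi_tags)
        with open(os.path.join(sdir, "metadata.json"), "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "series_uid": anon.series_uid,
                    "modality": anon.modality,
                    "key_values": anon.key_values,
                    "phi_removed": anon.phi_removed,
                },
                fh,
                indent=1,
            )
        write_mhd(vol, os.path.join(sdir, "volume.mhd"))
        voxel_labels = [
            l for l in latest.series_labels.get(ref.series_uid, ()) if isinstance(l, VoxelLabel)
        ]
        if voxel_labels:
            ldir = os.path.join(sdir, "labels")
            os.makedirs(ldir, exist_ok=True)
            for label in voxel_labels:
                grid = label_to_volume(label, ref.dims)
                write_mhd(
                    Volume(grid, spacing=vol.spacing, origin=vol.origin,
                           row_cosine=vol.row_cosine, col_cosine=vol.col_cosine),
                    os.path.join(ldir, f"{label.name}.mhd"),
                )
    return dest


def import_case(
    src: str | os.PathLike,
) -> tuple[ClinicalCase, dict[str, tuple[SeriesMetadata, Volume]]]:
    """Reconstruct a case (and its series volumes) from an archive.

    Structural problems are reported together in one :class:`CaseError`.
    """
    src = os.fspath(src)
    problems: list[str] = []
    case_path = os.path.join(src, "case.json")
    if not os.path.exists(case_path):
        raise CaseError(f"malformed archive: missing case.json in {src}")
    with open(case_path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("case_id", "project_id", "domain", "series", "revisions"):
        if key not in doc:
            problems.append(f"case.json missing {key!r}")
    if problems:
        raise CaseError("malformed archive: " + "; ".join(problems))

    series: dict[str, tuple[SeriesMetadata, Volume]] = {}
    refs: list[SeriesRef] = []
    for entry in doc["series"]:
        uid = entry["series_uid"]
        sdir = os.path.join(src, "series", uid)
        mpath = os.path.join(sdir, "metadata.json")
        vpath = os.path.join(sdir, "volume.mhd")
        if not os.path.exists(mpath):
            problems.append(f"missing {mpath}")
            continue
        if not os.path.exists(vpath):
            problems.append(f"missing {vpath}")
            continue
        with open(mpath, "r", encoding="utf-8") as fh:
            mdoc = json.load(fh)
        meta = SeriesMetadata(
            series_uid=mdoc["series_uid"],
            modality=mdoc["modality"],
            key_values=[tuple(kv) for kv in mdoc["key_values"]],
            phi_removed=mdoc["phi_removed"],
        )
        vol = read_mhd(vpath)
        series[uid] = (meta, vol)
        refs.append(SeriesRef(uid, entry["fingerprint"], tuple(entry["dims"])))
    if problems:
        raise CaseError("malformed archive: " + "; ".join(problems))

    revisions = [
        Revision(
            creator=r["creator"],
            timestamp=r["timestamp"],
            description=r["description"],
            case_attributes=r["case_attributes"],
            series_labels={
                uid: tuple(_label_from_json(l) for l in labels)
                for uid, labels in r["series_labels"].items()
            },
        )
        for r in doc["revisions"]
    ]
    case = ClinicalCase(
        case_id=doc["case_id"],
        project_id=doc["project_id"],
        domain=doc["domain"],
        series_refs=refs,
        revisions=revisions,
    )
    return case, series
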