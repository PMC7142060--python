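"""JSON-document store with domain-based access control.

A desk-scale persistence layer: a directory of JSON documents plus an
image-repository tree of MetaImage volumes. Attribute documents are stored
verbatim (schema-flexible). Every document write is crash-consistent at
single-document granularity: write-to-temp then atomic rename.

Access control follows the series ``domain`` model: each stored series
carries a domain string, and a user sees only series whose domain is in
their domain set (admins see all).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field

from .db import ClinicalCase, content_fingerprint, new_case_id
from .dicom_io import SeriesMetadata
from .mhd import read_mhd, write_mhd
from .volume import Volume

ROLES = ("annotator", "operator", "admin")


class StoreError(ValueError):
    pass


class AccessError(StoreError):
    pass


@dataclass(frozen=True)
class UserContext:
    """Who is asking: identity, visible domains, and roles."""

    user_id: str
    domains: frozenset[str] = frozenset()
    roles: frozenset[str] = frozenset({"annotator"})

    def __post_init__(self) -> None:
        if not self.user_id:
            raise StoreError("user_id must be non-empty")
        object.__setattr__(self, "domains", frozenset(self.domains))
        object.__setattr__(self, "roles", frozenset(self.roles))
        unknown = self.roles - set(ROLES)
        if unknown:
            raise StoreError(f"unknown role(s) {sorted(unknown)}; allowed: {ROLES}")

    @property
    def is_admin(self) -> bool:
        return "admin" in self.roles

    def can_see(self, domain: str) -> bool:
        return self.is_admin or domain in self.domains


@dataclass(frozen=True)
class RepositoryEntry:
    series_uid: str
    domain: str
    storage_path: str
    fingerprint: str
    version: int = 1


def atomic_write_json(path: str, doc) -> None:
    """Write-to-temp + atomic rename: a reader sees the old or the new
    document, never a torn one."""
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def access_filter(user: UserContext, entries) -> list:
    """Entries visible to the user: domain membership, admins see all."""
    return [e for e in entries if user.can_see(e.domain)]


class DocumentStore:
    """Filesystem store: ``series/`` image repository + JSON documents."""

    def __init__(self, root: str | os.PathLike):
        self.root = os.fspath(root)
        os.makedirs(os.path.join(self.root, "series"), exist_ok=True)
        os.makedirs(os.path.join(self.root, "cases"), exist_ok=True)

    # -- series -------------------------------------------------------

    def _series_dir(self, uid: str) -> str:
        return os.path.join(self.root, "series", uid)

    def _index_path(self, uid: str) -> str:
        return os.path.join(self._series_dir(uid), "entry.json")

    def store_series(
        self,
        volume: Volume,
        meta: SeriesMetadata,
        domain: str,
        user: UserContext,
    ) -> RepositoryEntry:
        """Persist a series (operator/admin only).

        Re-storing identical content is a no-op; different content bumps
        the entry version (dependent cases will then trip their integrity
        check against the stored fingerprint).
        """
        if not ({"operator", "admin"} & user.roles):
            raise AccessError(
                f"user {user.user_id!r} lacks the operator/admin role required to store series"
            )
        fp = content_fingerprint(volume)
        existing = self.get_entry(meta.series_uid)
        if existing is not None and existing.fingerprint == fp:
            return existing
        version = 1 if existing is None else existing.version + 1
        sdir = self._series_dir(meta.series_uid)
        os.makedirs(sdir, exist_ok=True)
        write_mhd(volume, os.path.join(sdir, "volume.mhd"))
        entry = RepositoryEntry(
            series_uid=meta.series_uid,
            domain=domain,
            storage_path=sdir,
            fingerprint=fp,
            version=version,
        )
        atomic_write_json(
            self._index_path(meta.series_uid),
            {
                "series_uid": entry.series_uid,
                "domain": entry.domain,
                "storage_path": entry.storage_path,
                "fingerprint": entry.fingerprint,
                "version": entry.version,
                "metadata": {
                    "modality": meta.modality,
                    "key_values": meta.key_values,
                    "phi_removed": meta.phi_removed,
                },
            },
        )
        return entry

    def get_entry(self, uid: str) -> RepositoryEntry | None:
        path = self._index_path(uid)
        if not os.path.exists(path):
            return None
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return RepositoryEntry(
            series_uid=doc["series_uid"],
            domain=doc["domain"],
            storage_path=doc["storage_path"],
            fingerprint=doc["fingerprint"],
            version=doc["version"],
        )

    def list_entries(self, user: UserContext | None = None) -> list[RepositoryEntry]:
        entries = []
        sroot = os.path.join(self.root, "series")
        for uid in sorted(os.listdir(sroot)):
            entry = self.get_entry(uid)
            if entry is not None:
                entries.append(entry)
        if user is not None:
            entries = access_filter(user, entries)
        return entries

    def fetch_series(
        self, uid: str, user: UserContext
    ) -> tuple[SeriesMetadata, Volume, str]:
        """Load a stored series, enforcing domain visibility."""
        entry = self.get_entry(uid)
        if entry is None:
            raise StoreError(f"unknown series {uid!r}")
        if not user.can_see(entry.domain):
            raise AccessError(
                f"access denied: series {uid} has domain {entry.domain!r} which is "
                f"not in {sorted(user.domains)}"
            )
        with open(self._index_path(uid), "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        meta = SeriesMetadata(
            series_uid=uid,
            modality=doc["metadata"]["modality"],
            key_values=[tuple(kv) for kv in doc["metadata"]["key_values"]],
            phi_removed=doc["metadata"]["phi_removed"],
        )
        volume = read_mhd(os.path.join(entry.storage_path, "volume.mhd"))
        return meta, volume, entry.domain

    def series_lookup(self, user: UserContext):
        """Adapter for :class:`~cadkit.harness.JobManager`: uid ->
        (meta, volume, domain) or None."""

        def lookup(uid: str):
            entry = self.get_entry(uid)
            if entry is None:
                return None
            with open(self._index_path(uid), "r", encoding="utf-8") as fh:
                doc = json.load(fh)
            meta = SeriesMetadata(
                series_uid=uid,
                modality=doc["metadata"]["modality"],
                key_values=[tuple(kv) for kv in doc["metadata"]["key_values"]],
                phi_removed=doc["metadata"]["phi_removed"],
            )
            volume = read_mhd(os.path.join(entry.storage_path, "volume.mhd"))
            return meta, volume, entry.domain

        return lookup

    # -- cases --------------------------------------------------------

    def save_case(self, case: ClinicalCase) -> str:
        """Persist a case document; a colliding case_id gets a fresh one
        (fresh store identity on import)."""
        from .db import export_case  # local import to avoid cycles

        path = os.path.join(self.root, "cases", f"{case.case_id}.json")
        if os.path.exists(path):
            case.case_id = new_case_id()
            path = os.path.join(self.root, "cases", f"{case.case_id}.json")
        # reuse the archive JSON shape for the stored document
        from .db import _label_to_json

        doc = {
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
        atomic_write_json(path, doc)
        return path

    def load_case(self, case_id: str) -> ClinicalCase:
        from .db import Revision, SeriesRef, _label_from_json

        path = os.path.join(self.root, "cases", f"{case_id}.json")
        if not os.path.exists(path):
            raise StoreError(f"unknown case {case_id!r}")
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return ClinicalCase(
            case_id=doc["case_id"],
            project_id=doc["project_id"],
            domain=doc["domain"],
            series_refs=[
                SeriesRef(s["series_uid"], s["fingerprint"], tuple(s["dims"]))
                for s in doc["series"]
            ],
            revisions=[
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
            ],
        )

    def list_cases(self) -> list[str]:
        croot = os.path.join(self.root, "cases")
        return sorted(f[:-5] for f in os.listdir(croot) if f.endswith(".json"))
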