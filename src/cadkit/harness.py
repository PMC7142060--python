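"""CAD plugin execution harness: sequential job manager, sandbox contract,
lesion-candidate results and clinical feedback.

Plugins never see DICOM files or patient information. In the preprocessing
phase each job's temporary work directory is populated with, per input
series, a raw volume + MetaImage header and a plain-text ``metadata.txt``
of selected non-PHI header values; the plugin runs in a sandbox that can
only touch that directory (and, under the container runner, has no network)
and writes ``out/results.json`` with ranked lesion candidates.

Jobs are strictly sequential and FIFO; status moves only along
``in_queue -> processing -> finished|failed``.
"""

from __future__ import annotations

import json
import os
import shutil
import subprocess
import sys
import tempfile
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dicom_io import DEFAULT_PHI_TAGS, SeriesMetadata
from .mhd import read_mhd, write_mhd
from .volume import Volume

FEEDBACK_CLASSES = ("known_TP", "missed_TP", "FP", "pending")

#: metadata keys exposed to plugins by default — never identity attributes;
#: the PHI list is subtracted afterwards regardless.
DEFAULT_PLUGIN_TAGS = (
    "Modality",
    "SeriesInstanceUID",
    "Rows",
    "Columns",
    "PixelSpacing",
    "SliceThickness",
    "KVP",
    "RepetitionTime",
    "EchoTime",
    "MagneticFieldStrength",
)

RESULT_SCHEMA_VERSION = 1


class HarnessError(ValueError):
    pass


class DomainAccessError(HarnessError):
    """Requester's domain list does not cover a series' domain."""


@dataclass(frozen=True)
class PluginManifest:
    """How to run one CAD plugin.

    ``command`` (argv list) selects the subprocess runner; ``image``
    (container reference) selects the container runner.
    """

    plugin_id: str
    version: str
    command: tuple[str, ...] | None = None
    image: str | None = None
    expected_inputs: int = 1
    result_schema_version: int = RESULT_SCHEMA_VERSION

    @property
    def key(self) -> str:
        return f"{self.plugin_id}@{self.version}"


@dataclass(frozen=True)
class LesionCandidate:
    rank: int
    location: tuple[int, int, int]
    confidence: float
    volume_mm3: float | None = None


@dataclass
class FeedbackEntry:
    """One user's per-candidate classification plus false-negative marks."""

    user: str
    per_candidate: dict[int, str]
    false_negatives: list[tuple[int, int, int]] = field(default_factory=list)
    timestamp: float = field(default_factory=time.time)


@dataclass
class PluginJob:
    job_id: str
    plugin_id: str
    series_uids: list[str]
    status: str = "in_queue"  # in_queue -> processing -> finished | failed
    work_dir: str | None = None
    results: list[LesionCandidate] = field(default_factory=list)
    displays: list = field(default_factory=list)
    feedback: list[FeedbackEntry] = field(default_factory=list)
    queued: float = 0.0
    started: float | None = None
    ended: float | None = None
    input_dims: tuple[int, int, int] | None = None
    error: str | None = None
    log: str = ""


# --- toy detector -----------------------------------------------------

def toy_blob_detector(
    volume: Volume, threshold: float, min_voxels: int
) -> list[LesionCandidate]:
    """Reference detector used in place of clinical CAD algorithms.

    Finds 26-connected components of voxels strictly above ``threshold``,
    keeps those with at least ``min_voxels`` voxels, and ranks them by
    descending voxel count (ties broken by ascending centroid z, y, x).
    Location is the rounded centroid; confidence the component's mean
    stored intensity.
    """
    mask = volume.data > threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood
    labelled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    counts = ndimage.sum_labels(mask, labelled, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(mask, labelled, index=range(1, n + 1))
    means = ndimage.mean(volume.data, labelled, index=range(1, n + 1))
    voxel_mm3 = float(np.prod(volume.spacing))
    comps = [
        (int(c), cen, float(m))
        for c, cen, m in zip(counts, centroids, means)
        if c >= min_voxels
    ]
    comps.sort(key=lambda t: (-t[0], t[1][2], t[1][1], t[1][0]))
    return [
        LesionCandidate(
            rank=i + 1,
            location=tuple(int(v) for v in np.rint(cen)),
            confidence=m,
            volume_mm3=c * voxel_mm3,
        )
        for i, (c, cen, m) in enumerate(comps)
    ]


# --- sandbox runners --------------------------------------------------

class SubprocessRunner:
    """Plain-subprocess sandbox for local plugins and test environments.

    The plugin command is executed with the job's work directory as its
    working directory — the contract is that it reads ``series/*/`` and
    writes only under ``out/``.
    """

    def run(self, manifest: PluginManifest, work_dir: str) -> tuple[int, str]:
        if not manifest.command:
            raise HarnessError(f"plugin {manifest.key} has no local command")
        proc = subprocess.run(
            list(manifest.command),
            cwd=work_dir,
            capture_output=True,
            text=True,
            timeout=600,
        )
        return proc.returncode, proc.stdout + proc.stderr


class ContainerRunner:
    """Container sandbox: no network, a single bind mount of the work dir.

    Requires a ``docker``-compatible CLI on PATH.
    """

    def __init__(self, docker_cmd: str = "docker", mount_point: str = "/workdir"):
        self.docker_cmd = docker_cmd
        self.mount_point = mount_point

    def build_args(self, manifest: PluginManifest, work_dir: str) -> list[str]:
        if not manifest.image:
            raise HarnessError(f"plugin {manifest.key} has no container image")
        return [
            self.docker_cmd,
            "run",
            "--rm",
            "--network", "none",
            "-v", f"{os.path.abspath(work_dir)}:{self.mount_point}",
            "-w", self.mount_point,
            manifest.image,
        ]

    def run(self, manifest: PluginManifest, work_dir: str) -> tuple[int, str]:
        if shutil.which(self.docker_cmd) is None:
            raise HarnessError(f"container runner unavailable: {self.docker_cmd} not on PATH")
        proc = subprocess.run(
            self.build_args(manifest, work_dir),
            capture_output=True,
            text=True,
            timeout=600,
        )
        return proc.returncode, proc.stdout + proc.stderr


# --- results parsing --------------------------------------------------

def parse_results(doc: dict, dims: tuple[int, int, int]) -> tuple[list[LesionCandidate], list]:
    """Validate a plugin's ``results.json`` document.

    Ranks must be unique and contiguous from 1; locations within dims.
    """
    if not isinstance(doc, dict) or "candidates" not in doc:
        raise HarnessError("results.json must be an object with a 'candidates' list")
    cands = doc["candidates"]
    if not isinstance(cands, list):
        raise HarnessError("'candidates' must be a list")
    out = []
    for c in cands:
        try:
            rank = int(c["rank"])
            loc = tuple(int(v) for v in c["location_voxel"])
            conf = float(c["confidence"])
        except (KeyError, TypeError, ValueError) as exc:
            raise HarnessError(f"malformed candidate {c!r}: {exc}") from exc
        if len(loc) != 3 or not all(0 <= v < n for v, n in zip(loc, dims)):
            raise HarnessError(f"candidate rank {rank}: location {loc} outside dims {dims}")
        out.append(
            LesionCandidate(
                rank=rank,
                location=loc,
                confidence=conf,
                volume_mm3=float(c["volume_mm3"]) if c.get("volume_mm3") is not None else None,
            )
        )
    ranks = sorted(c.rank for c in out)
    if ranks != list(range(1, len(out) + 1)):
        raise HarnessError(f"ranks must be unique and contiguous from 1, got {ranks}")
    return sorted(out, key=lambda c: c.rank), list(doc.get("displays", []))


# --- job manager ------------------------------------------------------

class JobManager:
    """Sequential FIFO job manager over a series lookup.

    ``series_lookup`` maps series UID to ``(SeriesMetadata, Volume,
    domain)``. At most one job is in ``processing`` at any time.
    """

    def __init__(
        self,
        series_lookup,
        root: str | None = None,
        plugin_tags=DEFAULT_PLUGIN_TAGS,
        phi_tags=DEFAULT_PHI_TAGS,
    ):
        self._lookup = series_lookup
        self.root = root or tempfile.mkdtemp(prefix="cadkit-jobs-")
        self.plugin_tags = tuple(plugin_tags)
        self.phi_tags = frozenset(phi_tags)
        self.plugins: dict[str, PluginManifest] = {}
        self.queue: list[PluginJob] = []
        self.jobs: dict[str, PluginJob] = {}
        self._counter = 0

    def register_plugin(self, manifest: PluginManifest) -> None:
        if manifest.key in self.plugins:
            raise HarnessError(f"plugin {manifest.key} already registered")
        self.plugins[manifest.plugin_id] = manifest
        self.plugins[manifest.key] = manifest

    def enqueue_job(self, plugin_id: str, series_uids: list[str], user) -> PluginJob:
        """Queue one plugin execution; the requester's domain list must
        contain every series' domain (admins are exempt)."""
        if plugin_id not in self.plugins:
            raise HarnessError(f"unknown plugin {plugin_id!r}")
        for uid in series_uids:
            entry = self._lookup(uid)
            if entry is None:
                raise HarnessError(f"unknown series {uid!r}")
            domain = entry[2]
            is_admin = "admin" in getattr(user, "roles", ())
            if not is_admin and domain not in getattr(user, "domains", ()):
                raise DomainAccessError(
                    f"access denied: series {uid} has domain {domain!r} which is "
                    f"not in the requester's domain list {sorted(user.domains)}"
                )
        self._counter += 1
        job = PluginJob(
            job_id=f"job-{self._counter:06d}",
            plugin_id=plugin_id,
            series_uids=list(series_uids),
            queued=time.time(),
        )
        self.queue.append(job)
        self.jobs[job.job_id] = job
        return job

    def prepare_job_inputs(self, job: PluginJob) -> str:
        """Populate the job's work directory: per series ``volume.mhd`` +
        ``volume.raw`` + ``metadata.txt`` (selected tags minus PHI), plus a
        writable ``out/``. No DICOM file and no PHI value is present."""
        if job.status != "in_queue":
            raise HarnessError(f"job {job.job_id} is {job.status}, expected in_queue")
        work_dir = os.path.join(self.root, job.job_id)
        os.makedirs(os.path.join(work_dir, "out"), exist_ok=True)
        for i, uid in enumerate(job.series_uids):
            meta, volume, _domain = self._lookup(uid)
            sdir = os.path.join(work_dir, "series", str(i))
            os.makedirs(sdir, exist_ok=True)
            write_mhd(volume, os.path.join(sdir, "volume.mhd"))
            lines = [
                f"{k} = {v}"
                for k, v in meta.key_values
                if k in self.plugin_tags and k not in self.phi_tags
            ]
            with open(os.path.join(sdir, "metadata.txt"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(lines) + "\n")
            if i == 0:
                job.input_dims = volume.dims
        job.work_dir = work_dir
        return work_dir

    def run_next_job(self, runner) -> PluginJob:
        """Run the oldest queued job to completion in the given sandbox.

        On success ``out/results.json`` is parsed into candidates and the
        job finishes; a nonzero exit or malformed results fails the job
        with the log captured — the queue then proceeds to the next job.
        """
        if any(j.status == "processing" for j in self.jobs.values()):
            raise HarnessError("another job is already processing")
        if not self.queue:
            raise HarnessError("queue is empty")
        job = self.queue.pop(0)
        try:
            if job.work_dir is None:
                self.prepare_job_inputs(job)
        except Exception as exc:  # preprocessing failure
            job.status = "failed"
            job.error = f"preprocessing error: {exc}"
            job.started = job.ended = time.time()
            return job
        job.status = "processing"
        job.started = time.time()
        manifest = self.plugins[job.plugin_id]
        try:
            code, log = runner.run(manifest, job.work_dir)
            job.log = log
            if code != 0:
                raise HarnessError(f"plugin exited with code {code}")
            results_path = os.path.join(job.work_dir, "out", "results.json")
            if not os.path.exists(results_path):
                raise HarnessError("plugin produced no out/results.json")
            with open(results_path, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
            job.results, job.displays = parse_results(doc, job.input_dims)
            job.status = "finished"
        except Exception as exc:
            job.status = "failed"
            job.error = str(exc)
        finally:
            job.ended = time.time()
            with open(os.path.join(job.work_dir, "job.log"), "w", encoding="utf-8") as fh:
                fh.write(job.log or "")
                if job.error:
                    fh.write(f"\nERROR: {job.error}\n")
        return job


def record_feedback(job: PluginJob, entry: FeedbackEntry) -> PluginJob:
    """Append a feedback entry iff it classifies every displayed candidate
    into exactly one of the four classes and every false-negative mark
    lies inside the volume."""
    if job.status != "finished":
        raise HarnessError(f"feedback requires a finished job, status is {job.status}")
    ranks = {c.rank for c in job.results}
    given = set(entry.per_candidate)
    unknown = given - ranks
    if unknown:
        raise HarnessError(f"feedback references unknown rank(s) {sorted(unknown)}")
    missing = ranks - given
    if missing:
        raise HarnessError(f"feedback incomplete: unclassified rank(s) {sorted(missing)}")
    bad = {r: c for r, c in entry.per_candidate.items() if c not in FEEDBACK_CLASSES}
    if bad:
        raise HarnessError(
            f"unknown feedback class(es) {bad}; allowed: {FEEDBACK_CLASSES}"
        )
    if job.input_dims is not None:
        for loc in entry.false_negatives:
            if len(loc) != 3 or not all(0 <= v < n for v, n in zip(loc, job.input_dims)):
                raise HarnessError(
                    f"false-negative location {tuple(loc)} outside dims {job.input_dims}"
                )
    job.feedback.append(entry)
    return job


def summarize_feedback(jobs) -> dict[str, dict[str, int]]:
    """Per-plugin counts of each feedback class plus false-negative marks.

    ``candidates_with_feedback`` equals the sum of the four class counts
    (totals conserve under any partition of the entries).
    """
    summary: dict[str, dict[str, int]] = {}
    for job in jobs:
        row = summary.setdefault(
            job.plugin_id,
            {c: 0 for c in FEEDBACK_CLASSES} | {"FN_marks": 0, "candidates_with_feedback": 0},
        )
        for entry in job.feedback:
            for cls in entry.per_candidate.values():
                row[cls] += 1
                row["candidates_with_feedback"] += 1
            row["FN_marks"] += len(entry.false_negatives)
    return summary
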