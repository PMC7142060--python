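"""Job manager, sandbox contract, toy detector and feedback bookkeeping."""

from __future__ import annotations

import json
import os
import sys

import numpy as np
import pytest

from cadkit import (
    FeedbackEntry,
    JobManager,
    Lesion,
    PluginManifest,
    SubprocessRunner,
    SyntheticSpec,
    UserContext,
    load_dicom_series,
    record_feedback,
    summarize_feedback,
    toy_blob_detector,
)
from cadkit.harness import ContainerRunner, DomainAccessError, HarnessError
from cadkit.synthetic import generate_synthetic_series, spec_volume
from cadkit.volume import Volume

from .conftest import enumerate_sphere_voxels

TOY_COMMAND = (sys.executable, "-m", "cadkit.toy_plugin", "--threshold", "200", "--min-voxels", "5")


def make_manager(tmp_path, *series_entries):
    """series_entries: (uid, volume, meta, domain) tuples."""
    table = {uid: (meta, vol, domain) for uid, vol, meta, domain in series_entries}
    return JobManager(lambda uid: table.get(uid), root=str(tmp_path / "jobs"))


@pytest.fixture
def loaded_series(two_lesion_series):
    vol, meta = load_dicom_series(two_lesion_series)
    return meta.series_uid, vol, meta


@pytest.fixture
def manager(tmp_path, loaded_series):
    uid, vol, meta = loaded_series
    mgr = make_manager(tmp_path, (uid, vol, meta, "siteA"))
    mgr.register_plugin(PluginManifest("toy", "1", command=TOY_COMMAND))
    return mgr


SITE_A_USER = UserContext("rad", domains=frozenset({"siteA"}), roles=frozenset({"annotator"}))


class TestEnqueue:
    def test_valid_request_queues(self, manager, loaded_series):
        job = manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        assert job.status == "in_queue"

    def test_unknown_plugin_rejected(self, manager, loaded_series):
        with pytest.raises(HarnessError, match="unknown plugin"):
            manager.enqueue_job("nope", [loaded_series[0]], SITE_A_USER)

    def test_domain_mismatch_rejected_naming_rule(self, manager, loaded_series):
        outsider = UserContext("ext", domains=frozenset({"siteB"}))
        with pytest.raises(DomainAccessError, match="domain 'siteA'"):
            manager.enqueue_job("toy", [loaded_series[0]], outsider)

    def test_admin_bypasses_domain(self, manager, loaded_series, admin_user):
        job = manager.enqueue_job("toy", [loaded_series[0]], admin_user)
        assert job.status == "in_queue"

    def test_fifo_order(self, manager, loaded_series):
        ids = [
            manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER).job_id
            for _ in range(3)
        ]
        ran = [manager.run_next_job(SubprocessRunner()).job_id for _ in range(3)]
        assert ran == ids  # oracle: FIFO simulation == enqueue order


class TestPrepareInputs:
    def test_work_dir_contract(self, manager, loaded_series):
        uid, vol, meta = loaded_series
        job = manager.enqueue_job("toy", [uid], SITE_A_USER)
        work_dir = manager.prepare_job_inputs(job)
        sdir = os.path.join(work_dir, "series", "0")
        assert os.path.exists(os.path.join(sdir, "volume.mhd"))
        assert os.path.exists(os.path.join(sdir, "metadata.txt"))
        assert os.path.isdir(os.path.join(work_dir, "out"))
        raw = os.path.join(sdir, "volume.raw")
        assert os.path.getsize(raw) == int(np.prod(vol.dims)) * vol.data.dtype.itemsize

    def test_no_dicom_payloads_anywhere(self, manager, loaded_series):
        job = manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        work_dir = manager.prepare_job_inputs(job)
        for root, _, files in os.walk(work_dir):
            for name in files:
                with open(os.path.join(root, name), "rb") as fh:
                    head = fh.read(132)
                assert head[128:132] != b"DICM"

    def test_metadata_is_selected_minus_phi(self, manager, loaded_series):
        uid, vol, meta = loaded_series
        job = manager.enqueue_job("toy", [uid], SITE_A_USER)
        work_dir = manager.prepare_job_inputs(job)
        with open(os.path.join(work_dir, "series", "0", "metadata.txt")) as fh:
            keys = {line.split(" = ")[0] for line in fh if line.strip()}
        # oracle: set arithmetic on the fixture's tags
        expected = (set(meta.keywords()) & set(manager.plugin_tags)) - manager.phi_tags
        assert keys == expected
        assert "PatientName" not in keys and "PatientID" not in keys

    def test_phi_values_absent_from_metadata_text(self, manager, loaded_series):
        uid, vol, meta = loaded_series
        job = manager.enqueue_job("toy", [uid], SITE_A_USER)
        work_dir = manager.prepare_job_inputs(job)
        text = open(os.path.join(work_dir, "series", "0", "metadata.txt")).read()
        for phi_kw in ("Synthetic^Subject", "SYN0001", "Synthetic Hospital"):
            assert phi_kw not in text


class TestRunJob:
    def test_planted_lesions_recovered_end_to_end(self, manager, loaded_series, two_lesion_spec):
        job = manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        job = manager.run_next_job(SubprocessRunner())
        assert job.status == "finished", job.error
        assert len(job.results) == len(two_lesion_spec.lesions)
        centers = sorted(l.center for l in two_lesion_spec.lesions)
        got = sorted(c.location for c in job.results)
        for truth, found in zip(centers, got):
            assert max(abs(a - b) for a, b in zip(truth, found)) <= 1

    def test_ranks_follow_component_size(self, manager, loaded_series):
        job = manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        job = manager.run_next_job(SubprocessRunner())
        # lesion at (8,8,6) r=4.5 is larger than (24,24,14) r=3.0
        assert job.results[0].location == (8, 8, 6)
        assert [c.rank for c in job.results] == [1, 2]

    def test_failing_plugin_fails_job_and_queue_proceeds(self, tmp_path, loaded_series):
        uid, vol, meta = loaded_series
        mgr = make_manager(tmp_path, (uid, vol, meta, "siteA"))
        mgr.register_plugin(
            PluginManifest("bad", "1", command=(sys.executable, "-c", "import sys; print('boom'); sys.exit(3)"))
        )
        mgr.register_plugin(PluginManifest("toy", "1", command=TOY_COMMAND))
        mgr.enqueue_job("bad", [uid], SITE_A_USER)
        mgr.enqueue_job("toy", [uid], SITE_A_USER)
        failed = mgr.run_next_job(SubprocessRunner())
        assert failed.status == "failed"
        assert "code 3" in failed.error
        assert "boom" in failed.log
        assert os.path.exists(os.path.join(failed.work_dir, "job.log"))
        ok = mgr.run_next_job(SubprocessRunner())
        assert ok.status == "finished"

    def test_sequential_jobs_do_not_overlap(self, manager, loaded_series):
        manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        manager.enqueue_job("toy", [loaded_series[0]], SITE_A_USER)
        first = manager.run_next_job(SubprocessRunner())
        second = manager.run_next_job(SubprocessRunner())
        assert first.ended <= second.started

    def test_malformed_results_fail_job(self, tmp_path, loaded_series):
        uid, vol, meta = loaded_series
        mgr = make_manager(tmp_path, (uid, vol, meta, "siteA"))
        writer = (
            sys.executable, "-c",
            "import json; json.dump({'candidates': [{'rank': 2, 'location_voxel': [0,0,0], "
            "'confidence': 1.0}]}, open('out/results.json','w'))",
        )
        mgr.register_plugin(PluginManifest("badjson", "1", command=writer))
        mgr.enqueue_job("badjson", [uid], SITE_A_USER)
        job = mgr.run_next_job(SubprocessRunner())
        assert job.status == "failed"
        assert "contiguous" in job.error

    def test_container_runner_args_disable_network_single_mount(self, tmp_path):
        runner = ContainerRunner()
        manifest = PluginManifest("c", "1", image="example/cad:1")
        args = runner.build_args(manifest, str(tmp_path))
        assert "--network" in args and args[args.index("--network") + 1] == "none"
        mounts = [a for a in args if str(tmp_path) in a]
        assert len(mounts) == 1


class TestToyBlobDetector:
    def test_all_below_threshold_empty(self):
        vol = Volume(np.full((6, 6, 6), 10, np.int16), spacing=(1, 1, 1))
        assert toy_blob_detector(vol, 200, 1) == []

    def test_two_spheres_ranked_by_size(self):
        spec = SyntheticSpec(
            dims=(30, 30, 20),
            lesions=[Lesion((8, 8, 8), 3.0, 500), Lesion((22, 22, 12), 2.0, 600)],
        )
        cands = toy_blob_detector(spec_volume(spec), 200, 10)
        assert len(cands) == 2
        assert cands[0].location == (8, 8, 8) and cands[1].location == (22, 22, 12)
        big = len(enumerate_sphere_voxels(spec.dims, spec.spacing, (8, 8, 8), 3.0))
        assert cands[0].volume_mm3 == pytest.approx(big)
        assert cands[0].confidence == pytest.approx(500.0)

    def test_min_voxels_filters_everything(self):
        spec = SyntheticSpec(dims=(20, 20, 10), lesions=[Lesion((10, 10, 5), 2.0, 500)])
        assert toy_blob_detector(spec_volume(spec), 200, 10_000) == []

    def test_tie_break_by_centroid_order(self):
        data = np.zeros((10, 10, 4), np.int16)
        data[1, 1, 1] = 300  # single-voxel components, equal size
        data[5, 5, 2] = 300
        vol = Volume(data, spacing=(1, 1, 1))
        cands = toy_blob_detector(vol, 200, 1)
        assert [c.location for c in cands] == [(1, 1, 1), (5, 5, 2)]


class TestFeedback:
    def _finished_job(self, manager, uid):
        manager.enqueue_job("toy", [uid], SITE_A_USER)
        return manager.run_next_job(SubprocessRunner())

    def test_complete_classification_accepted(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        entry = FeedbackEntry("rad1", {1: "known_TP", 2: "FP"})
        record_feedback(job, entry)
        assert job.feedback == [entry]

    def test_incomplete_rejected_listing_ranks(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        with pytest.raises(HarnessError, match=r"unclassified rank\(s\) \[2\]"):
            record_feedback(job, FeedbackEntry("rad1", {1: "known_TP"}))
        assert job.feedback == []

    def test_unknown_class_rejected(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        with pytest.raises(HarnessError, match="unknown feedback class"):
            record_feedback(job, FeedbackEntry("rad1", {1: "sub_TP", 2: "FP"}))

    def test_unknown_rank_rejected(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        with pytest.raises(HarnessError, match="unknown rank"):
            record_feedback(job, FeedbackEntry("rad1", {1: "FP", 2: "FP", 3: "FP"}))

    def test_fn_location_bounds_checked(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        with pytest.raises(HarnessError, match="outside dims"):
            record_feedback(
                job, FeedbackEntry("rad1", {1: "FP", 2: "FP"}, false_negatives=[(99, 0, 0)])
            )

    def test_multiple_users_append(self, manager, loaded_series):
        job = self._finished_job(manager, loaded_series[0])
        record_feedback(job, FeedbackEntry("rad1", {1: "known_TP", 2: "FP"}))
        record_feedback(job, FeedbackEntry("rad2", {1: "missed_TP", 2: "pending"}))
        assert [e.user for e in job.feedback] == ["rad1", "rad2"]


class TestSummarizeFeedback:
    def test_no_feedback_all_zero(self, manager, loaded_series):
        job = self._make_job(manager, loaded_series[0])
        summary = summarize_feedback([job])
        assert all(v == 0 for v in summary["toy"].values())

    def _make_job(self, manager, uid):
        manager.enqueue_job("toy", [uid], SITE_A_USER)
        return manager.run_next_job(SubprocessRunner())

    def test_direct_counts(self, manager, loaded_series):
        job = self._make_job(manager, loaded_series[0])
        record_feedback(job, FeedbackEntry("rad1", {1: "known_TP", 2: "pending"}, [(1, 1, 1)]))
        row = summarize_feedback([job])["toy"]
        assert (row["known_TP"], row["missed_TP"], row["FP"], row["pending"]) == (1, 0, 0, 1)
        assert row["FN_marks"] == 1
        assert row["candidates_with_feedback"] == 2

    def test_partition_conservation(self, manager, loaded_series):
        """Summaries over any split of the jobs add up to the whole."""
        rng = np.random.default_rng(17)
        jobs = [self._make_job(manager, loaded_series[0]) for _ in range(6)]
        classes = list(("known_TP", "missed_TP", "FP", "pending"))
        for job in jobs:
            for u in range(int(rng.integers(1, 4))):
                per = {c.rank: classes[rng.integers(0, 4)] for c in job.results}
                record_feedback(job, FeedbackEntry(f"u{u}", per))
        whole = summarize_feedback(jobs)["toy"]
        for _ in range(20):
            mask = rng.integers(0, 2, len(jobs)).astype(bool)
            left = summarize_feedback([j for j, m in zip(jobs, mask) if m]).get("toy", {})
            right = summarize_feedback([j for j, m in zip(jobs, mask) if not m]).get("toy", {})
            for key, total in whole.items():
                assert left.get(key, 0) + right.get(key, 0) == total
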