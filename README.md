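# cadkit

A headless Python toolkit for developing and validating computer-assisted
detection/diagnosis (CAD) software on radiological images. It provides the
computational core a CAD research platform needs, as a library plus a thin
CLI — no web stack, no database server:

* **Image I/O** — classic one-file-per-slice DICOM series are loaded into
  geometry-complete volumes (slices sorted by position along the slice
  normal, rescale applied, uniform slice spacing enforced); volumes are
  interchanged as ITK MetaImage (`.mhd` + `.raw`) in a strict, bit-exact
  dialect; a synthetic-series generator plants spherical lesions with known
  centres over Gaussian background noise, so every fixture carries its own
  ground truth.
* **Reconstruction** — one deterministic multiplanar-reconstruction (MPR)
  kernel: orthogonal sections are exact grid-plane copies, oblique planes
  are resampled with nearest-neighbour or trilinear interpolation
  (`output[j, i] = V(origin + i·u + j·v)`), and a window/level transform
  `g = round(clip((v − (L − W/2))/W, 0, 1)·255)` maps stored values to
  8-bit display gray (PNG export included).
* **Annotation database** — cases with globally unique ids grouped into
  projects; spacing-aware spherical brush painting of voxel labels stored
  as tight bounding boxes; attributes validated against a flat JSON-Schema
  subset; an append-only revision history; SHA-256 content fingerprints
  that flag any post-registration change to a series; anonymized case
  export/import.
* **Plugin harness** — a strictly sequential FIFO job manager that prepares
  a sandboxed work directory per job (MetaImage volume + selected non-PHI
  metadata, never DICOM), runs the plugin via a subprocess or container
  runner (`--network none`, single bind mount), parses ranked lesion
  candidates, and collects per-candidate radiologist feedback
  (known TP / missed TP / FP / pending, plus false-negative marks).

It is aimed at researchers who need a reproducible desk-scale harness for
CAD algorithm development: plant lesions, run a detector under the exact
contract a clinical deployment would use, and keep gold-standard labels
with full history.

## Worked example

```python
import sys
from cadkit import (
    SyntheticSpec, Lesion, generate_synthetic_series, load_dicom_series,
    UserContext, DocumentStore, JobManager, PluginManifest, SubprocessRunner,
    FeedbackEntry, record_feedback, summarize_feedback,
)

# a 32x32x20 noise-free series with two planted spheres
spec = SyntheticSpec(
    dims=(32, 32, 20), spacing=(1.0, 1.0, 1.0), background_level=100,
    lesions=[Lesion((8, 8, 6), 4.5, 500), Lesion((24, 24, 14), 3.0, 600)],
    seed=7,
)
volume, meta = load_dicom_series(generate_synthetic_series(spec))

user = UserContext("op", domains=frozenset({"siteA"}), roles=frozenset({"operator"}))
store = DocumentStore("./demo-store")
store.store_series(volume, meta, "siteA", user)

mgr = JobManager(store.series_lookup(user))
mgr.register_plugin(PluginManifest(
    "toy-blob-detector", "1",
    command=(sys.executable, "-m", "cadkit.toy_plugin",
             "--threshold", "200", "--min-voxels", "5"),
))
mgr.enqueue_job("toy-blob-detector", [meta.series_uid], user)
job = mgr.run_next_job(SubprocessRunner())
print(job.status, [(c.rank, c.location, c.volume_mm3) for c in job.results])

record_feedback(job, FeedbackEntry("rad1", {1: "known_TP", 2: "FP"}))
print(summarize_feedback([job]))
```

Output:

```
finished [(1, (8, 8, 6), 389.0), (2, (24, 24, 14), 123.0)]
{'toy-blob-detector': {'known_TP': 1, 'missed_TP': 0, 'FP': 1, 'pending': 0,
 'FN_marks': 0, 'candidates_with_feedback': 2}}
```

Both planted spheres come back at exactly their planted centres, ranked by
size (389 voxels for the 4.5 mm sphere, 123 for the 3.0 mm one at 1 mm
isotropic spacing), and the feedback summary counts one known true
positive and one false positive.

The same flow is available from the shell:

```sh
cadkit --store ./demo-store --domains siteA --roles operator,annotator \
    synth generate --spec spec.json --seed 7 --out ./dicom
cadkit --store ./demo-store --domains siteA --roles operator import ./dicom --domain siteA
cadkit --store ./demo-store --domains siteA job enqueue --series <uid>
cadkit --store ./demo-store --domains siteA job run
cadkit --store ./demo-store --domains siteA feedback add <job-id> --classes 1=known_TP,2=FP
```

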