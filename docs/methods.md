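# Methods

This note records the conventions, models and numerical choices behind
cadkit, and what its synthetic fixtures do and do not establish about real
clinical data.

## Geometry and volume model

A volume is a scalar grid `data[x, y, z]` with spacing `(sx, sy, sz)` in
mm, a patient-space origin, and row/column direction cosines taken from
the source DICOM series. Patient coordinates follow the DICOM LPS
convention; voxel indices are 0-based and voxel `(i, j, k)` maps to
`origin + i·sx·row + j·sy·col + k·sz·normal`, i.e. voxel `(0,0,0)` sits
exactly at the origin. Supported element types are int16, uint16 and
uint8 — the types CAD plugins consume; rescale slope/intercept is applied
at load and rounded back into the integer type (a CT intercept of −1024
is exact under this rule).

Slice ordering is geometry-authoritative: slices sort by the projection of
ImagePositionPatient onto the slice normal, with InstanceNumber only as a
tie-break, because instance numbers can be renumbered while positions
cannot. Slice spacing is derived from adjacent position differences and
must be uniform to a relative tolerance of 1e-3; a non-uniform series is
rejected (naming the offending gap) rather than resampled, because the
plugin contract assumes a regular grid. A single-slice series defaults to
the stored SliceThickness, else 1.0 mm.

## MetaImage dialect

Volumes are interchanged as `.mhd` + `.raw` pairs in a deliberately narrow
dialect: uncompressed, local raw file, little-endian, element types
MET_SHORT / MET_USHORT / MET_UCHAR, raw buffer in x-fastest order.
Anything else (compressed data, file lists, big-endian, float types) is an
explicit rejection, never a best-effort read. The narrowness is the point:
plugins get a bit-exact, dependency-free contract. SimpleITK reads these
files identically, which the test suite uses as an independent
cross-check of the codec.

## Reconstruction kernel

One sampling kernel serves every consumer, so a section computed anywhere
is bit-identical to the same section computed anywhere else (determinism
is asserted by tests rather than assumed).

* Orthogonal sections are exact array copies of grid planes — lossless by
  construction.
* Oblique sections sample `output[j, i] = V(origin + i·u + j·v)` —
  sample-at-corner, with no half-pixel offset; this convention is stated
  explicitly because half-pixel conventions are the classic source of
  off-by-half bugs.
* Trilinear interpolation uses the mathematical 8-corner weights. A sample
  exactly on a voxel boundary gives zero weight to the far neighbour, and
  a zero-weight neighbour contributes nothing *even when it lies outside
  the volume* — this prevents fill-value bleeding at exact edges, and is
  the one place the kernel deliberately differs from
  `scipy.ndimage.map_coordinates`, which is why the kernel is implemented
  directly.
* Samples with any nonzero-weight neighbour out of bounds yield the fill
  value, which defaults to the volume minimum.
* Interpolation defaults to trilinear for oblique planes. This is an
  assumption about viewer-quality expectations, not a reconstruction of
  any particular viewer's behaviour.

Window/level maps stored values to display gray as
`round(clamp((v − (level − width/2))/width, 0, 1)·255)` with round-half-up
(so `v = level` maps to 128); the transform is monotone non-decreasing.

## Annotation model

Voxel labels are binary masks stored as a tight bounding box (offset +
size + mask) inside the series grid; tightness is re-established after
every mutation, and an unpainted label is legal with size `(0,0,0)`. The
brush is a sphere in millimetres — spacing-aware, so a 3 mm brush covers
more voxels along a 0.5 mm axis than a 2 mm one. Painting is idempotent
and erase is its inverse. Labels are stored run-length-encoded inside JSON
documents but exported as raw uint8 0/1 volumes for interchange. 2D
geometric annotations (ellipse/rectangle on an orthogonal plane) are
stored and round-tripped but never rasterized to voxels, since no
rasterization semantics would survive round-tripping unambiguously.

Attribute documents validate against a fixed flat subset of JSON Schema
(`type`, `properties`, `required`, `enum`, `minimum`, `maximum`; scalar
property types only). The subset is enforced up front: a schema using any
other keyword is rejected rather than half-validated. The validator is
part of this package's contract, implemented directly.

Cases are append-only: a revision, once appended, is never mutated, and
labels are stored by copy so later edits to a caller's label object cannot
reach into history. Case ids are random 160-bit hex strings; at desk
scale, collisions are treated as impossible (a store-level import that
does collide assigns a fresh id — archives keep their original id because
the archive is the interchange unit). Series content is fingerprinted at
case creation as SHA-256 over the slice count plus per-slice pixel buffers
in slice order; the integrity check warns exactly when pixel content or
image count changed, and reports a missing series distinctly.

Anonymization removes a configurable list of PHI attribute keywords
(default: patient name/ID/birth date/address, physicians, institution,
accession/station, plus all private tags) from the metadata record; pixel
data is never touched. The default list is a package choice — there is no
single canonical PHI enumeration — and can be replaced by a one-keyword-
per-line text file.

## Plugin harness

Jobs are strictly sequential and FIFO; status moves only along
`in_queue → processing → finished|failed`. Preprocessing writes, per input
series, a MetaImage pair and a `metadata.txt` of `key = value` lines drawn
from a configurable tag list (defaults to acquisition parameters, never
identity attributes) with the PHI list subtracted last — so plugins never
see DICOM files or patient information, which both removes the need for
plugins to parse DICOM and keeps PHI out of their reach. Two runners
implement one executor contract: a plain-subprocess runner (used by the
tests and the acceptance script) and a container runner that invokes a
Docker-compatible CLI with networking disabled and the job's work
directory as the only bind mount. Results arrive as `out/results.json`
(contract version 1): a `candidates` list with unique ranks contiguous
from 1, voxel locations, confidences and optional volumes, plus free-form
`displays`.

Feedback is the four-class taxonomy — known TP (lesion the reader found
anyway), missed TP (lesion the reader overlooked), FP, pending — plus
reader-marked false-negative locations. An entry is accepted only if every
displayed candidate is classified; entries are append-only per user and
no consensus rule is computed. (Some workflows add a fifth "sub TP"
class; the four-class model is implemented here.) Summaries conserve
counts under any partition of entries.

The bundled `toy_blob_detector` (26-connected components above a
threshold, filtered by minimum voxel count, ranked by descending size with
centroid-order tie-breaks) is a stand-in for clinical CAD algorithms: it
exists to exercise the harness contract end to end, not to detect real
lesions. Connected-component labelling is delegated to `scipy.ndimage`.

## Synthetic data

The generator emulates thin-slice series of the shapes typical of clinical
CAD input (e.g. 632×768×128 MR angiography, 512×512 CT), with a constant
background, optional Gaussian noise, and spherical lesions of stated
intensity whose voxelization is exact (a voxel is inside iff its centre is
within the radius in mm). One integer seed drives a single PRNG stream and
is recorded in the emitted metadata; a fixed seed yields byte-identical
DICOM payloads. Fixtures carry fake identity attributes precisely so the
anonymization and sandbox contracts have something real to strip.

What the fixtures do **not** emulate: real lesion morphology (spiculation,
ground-glass texture), partial-volume effects, scanner artefacts, gantry
tilt or non-axial orientations in the generated series, and realistic
intensity distributions. Passing tests therefore establish the
*contracts* — geometry handling, losslessness, sandboxing, bookkeeping,
exact recovery of ideal targets — not clinical detection performance.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run at desk scale as a design
choice: random volumes up to 16³ for kernel-equivalence checks (100
volume/plane pairs against a brute-force per-pixel resampler, max
absolute error required < 1e-9; measured ~1e-13), 50 MetaImage and 10
case-archive round trips, 20 pipeline replicates with 0–5 planted
lesions in 36×36×24 grids, 1000 randomized revision mutations, and 100
random feedback partitions. One ingestion test exercises the full
632×768×128 series shape. Direction cosines must be unit length and
orthogonal to 1e-6; voxel↔mm mappings are mutually inverse to 1e-9;
slice-gap uniformity tolerance is 1e-3 relative.

## Known limitations

* No DICOM network services (C-STORE/Query-Retrieve) — import is
  file-based.
* Uncompressed, monochrome, single-frame DICOM only.
* The job manager is intentionally single-lane; concurrency is out of
  scope.
* Role model (annotator/operator/admin) and the domain access-control
  string are a minimal stand-in for a full authorization service; the CLI
  takes the acting user as arguments rather than authenticating anyone.
* Persistence is a directory of JSON documents with atomic single-document
  writes; there is no multi-writer coordination.
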