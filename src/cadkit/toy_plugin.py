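"""Executable toy CAD plugin honouring the work-directory contract.

Run inside a prepared job work directory (``python -m cadkit.toy_plugin``):
reads ``series/0/volume.mhd``, detects bright blobs, and writes ranked
lesion candidates to ``out/results.json``. Stands in for real clinical
detectors when exercising the harness end to end.
"""

from __future__ import annotations

import argparse
import json
import os
import sys

from .harness import RESULT_SCHEMA_VERSION, toy_blob_detector
from .mhd import read_mhd


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--threshold", type=float, default=200.0)
    parser.add_argument("--min-voxels", type=int, default=5)
    parser.add_argument("--work-dir", default=".")
    args = parser.parse_args(argv)

    volume = read_mhd(os.path.join(args.work_dir, "series", "0", "volume.mhd"))
    candidates = toy_blob_detector(volume, args.threshold, args.min_voxels)
    doc = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "candidates": [
            {
                "rank": c.rank,
                "location_voxel": list(c.location),
                "confidence": c.confidence,
                "volume_mm3": c.volume_mm3,
            }
            for c in candidates
        ],
        "displays": [],
    }
    out_dir = os.path.join(args.work_dir, "out")
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "results.json"), "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    print(f"toy plugin: {len(candidates)} candidate(s)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
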