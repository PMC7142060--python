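"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: the
trilinear oracle maps patient points to voxel coordinates with explicit
origin/spacing arithmetic (identity orientation only) and loops pixel by
pixel; the sphere oracle enumerates voxel centres exhaustively.
"""

from __future__ import annotations

import numpy as np
import pytest

from cadkit import Lesion, SyntheticSpec, UserContext, Volume, generate_synthetic_series
from cadkit.synthetic import generate_volume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_volume(rng, max_dim=8, dtype=np.int16, spacing=None) -> Volume:
    dims = tuple(int(rng.integers(2, max_dim + 1)) for _ in range(3))
    if spacing is None:
        spacing = tuple(float(rng.uniform(0.5, 2.5)) for _ in range(3))
    info = np.iinfo(dtype)
    data = rng.integers(max(info.min, -1000), min(info.max, 1000), dims).astype(dtype)
    origin = tuple(float(rng.uniform(-20, 20)) for _ in range(3))
    return Volume(data=data, spacing=spacing, origin=origin)


def brute_force_trilinear(volume: Volume, origin, u, v, out_size) -> np.ndarray:
    """Per-pixel 8-neighbour weighted sum; identity orientation assumed.

    Independent of the engine: index mapping is written out as
    (point - origin) / spacing, and each of the 8 corners is summed in an
    explicit loop. Out-of-volume samples (a nonzero-weight neighbour out
    of bounds) yield the volume minimum.
    """
    w, h = out_size
    fill = float(volume.data.min())
    out = np.empty((h, w), dtype=np.float64)
    for j in range(h):
        for i in range(w):
            p = np.asarray(origin, float) + i * np.asarray(u, float) + j * np.asarray(v, float)
            c = (p - np.asarray(volume.origin)) / np.asarray(volume.spacing)
            f = np.floor(c).astype(int)
            t = c - f
            acc = 0.0
            ok = True
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        wgt = (
                            (t[0] if dx else 1 - t[0])
                            * (t[1] if dy else 1 - t[1])
                            * (t[2] if dz else 1 - t[2])
                        )
                        n = (f[0] + dx, f[1] + dy, f[2] + dz)
                        inb = all(0 <= n[a] < volume.dims[a] for a in range(3))
                        if wgt > 0 and not inb:
                            ok = False
                        if inb:
                            acc += wgt * float(volume.data[n])
            out[j, i] = acc if ok else fill
    return out


def enumerate_sphere_voxels(dims, spacing, center, radius_mm) -> set[tuple[int, int, int]]:
    """Exhaustive triple loop: voxels whose centre is within the radius."""
    hits = set()
    for x in range(dims[0]):
        for y in range(dims[1]):
            for z in range(dims[2]):
                d2 = sum(((c - k) * s) ** 2 for c, k, s in zip((x, y, z), center, spacing))
                if d2 <= radius_mm**2:
                    hits.add((x, y, z))
    return hits


@pytest.fixture
def two_lesion_spec() -> SyntheticSpec:
    """Noise-free fixture with two well-separated spheres (~389 and ~123
    voxels at 1 mm isotropic)."""
    return SyntheticSpec(
        dims=(32, 32, 20),
        spacing=(1.0, 1.0, 1.0),
        background_level=100,
        noise_sd=0.0,
        lesions=[Lesion((8, 8, 6), 4.5, 500), Lesion((24, 24, 14), 3.0, 600)],
        seed=7,
    )


@pytest.fixture
def two_lesion_series(two_lesion_spec):
    return generate_synthetic_series(two_lesion_spec)


@pytest.fixture
def two_lesion_truth(two_lesion_spec):
    return generate_volume(two_lesion_spec)


@pytest.fixture
def operator_user() -> UserContext:
    return UserContext("op", domains=frozenset({"siteA"}), roles=frozenset({"operator"}))


@pytest.fixture
def admin_user() -> UserContext:
    return UserContext("root", domains=frozenset(), roles=frozenset({"admin"}))
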