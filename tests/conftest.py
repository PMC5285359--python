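from __future__ import annotations

import numpy as np
import pytest

import mnctess as M


def random_instance(seed: int, n_min: int = 10, n_max: int = 50,
                    size: int = 64) -> np.ndarray:
    """Seeded random generator points strictly inside a size x size box."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    pts = rng.uniform(1.0, size - 1.0, size=(n, 2))
    # enforce pairwise separation so instances are never near-degenerate
    keep = [pts[0]]
    for p in pts[1:]:
        if min(np.hypot(*(p - q)) for q in keep) > 0.5:
            keep.append(p)
    return np.asarray(keep)


@pytest.fixture(scope="session")
def seeded_instances():
    """The 50 seeded random Voronoi instances used by the geometry checks."""
    return {s: random_instance(s) for s in range(50)}


@pytest.fixture(scope="session")
def canonical_suite():
    """(tiling, mncs) for the canonical 20-image blob fixture suite."""
    out = []
    for seed in range(20):
        img = M.make_blob_image(M.default_fixture_config(seed=seed))
        g = M.compute_gradient(img)
        pts = M.select_generating_points(g)
        tiling = M.build_tessellation(pts, (img.width, img.height))
        out.append((tiling, M.find_maximal_nucleus_clusters(tiling)))
    return out


@pytest.fixture(scope="session")
def grid_tiling():
    """3x3 grid of evenly spaced points in a 12x12 box (center degree 4)."""
    pts = [(2.0 + 4 * i, 2.0 + 4 * j) for j in range(3) for i in range(3)]
    return M.build_tessellation(pts, (12.0, 12.0))


@pytest.fixture(scope="session")
def two_point_tiling():
    return M.build_tessellation([(2.0, 5.0), (8.0, 5.0)], (10.0, 10.0))
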