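"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's code paths: nearest-point
labeling by exhaustive distance comparison, adjacency by all-pairs polygon
boundary intersection (shapely), areas by pixel-counting rasterization,
Renyi entropy by direct arithmetic, and antipodal matching by bitmask
dynamic programming over all maximal pairings.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon


def pixel_center_grid(width: int, height: int) -> np.ndarray:
    """(width*height, 2) array of pixel-center coordinates (x+.5, y+.5)."""
    ys, xs = np.mgrid[0:height, 0:width]
    return np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5]).astype(float)


def nearest_label_oracle(points: np.ndarray, width: int, height: int,
                         tie_tol: float = 1e-9):
    """Label each pixel center by its nearest generator (exhaustive).

    Returns (labels, decided) where decided is False for equidistant
    pixels (nearest two generators within tie_tol).
    """
    grid = pixel_center_grid(width, height)
    d = cdist(grid, points)
    part = np.partition(d, 1, axis=1)
    decided = (part[:, 1] - part[:, 0]) > tie_tol
    return d.argmin(axis=1), decided


def membership_labels(tiling) -> np.ndarray:
    """Label pixel centers by which region polygon covers them (-1 if none)."""
    import shapely

    w, h = int(tiling.bounds[0]), int(tiling.bounds[1])
    grid = pixel_center_grid(w, h)
    pts = shapely.points(grid[:, 0], grid[:, 1])
    labels = np.full(len(grid), -1)
    for i, verts in enumerate(tiling.regions):
        inside = shapely.covers(Polygon(verts), pts)
        labels[inside & (labels == -1)] = i
    return labels


def adjacency_oracle(tiling, eps: float = 1e-9) -> list[frozenset[int]]:
    """All-pairs shared-boundary-length adjacency from region polygons."""
    polys = [Polygon(v) for v in tiling.regions]
    n = len(polys)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if polys[i].intersection(polys[j]).length > eps:
                adj[i].add(j)
                adj[j].add(i)
    return [frozenset(a) for a in adj]


def dilation_adjacency_oracle(tiling) -> set[tuple[int, int]]:
    """Raster adjacency: region labels 4-connectivity-adjacent on the grid."""
    w, h = int(tiling.bounds[0]), int(tiling.bounds[1])
    labels, decided = nearest_label_oracle(tiling.coords, w, h)
    lab = labels.reshape(h, w)
    pairs = set()
    a, b = lab[:, :-1].ravel(), lab[:, 1:].ravel()
    pairs |= {(min(p, q), max(p, q)) for p, q in zip(a, b) if p != q}
    a, b = lab[:-1, :].ravel(), lab[1:, :].ravel()
    pairs |= {(min(p, q), max(p, q)) for p, q in zip(a, b) if p != q}
    return pairs


def raster_area_oracle(tiling) -> np.ndarray:
    """Per-region areas by counting nearest-generator pixel centers."""
    w, h = int(tiling.bounds[0]), int(tiling.bounds[1])
    labels, _ = nearest_label_oracle(tiling.coords, w, h)
    return np.bincount(labels, minlength=len(tiling.coords)).astype(float)


def renyi_direct(p, beta: float) -> float:
    """Direct-arithmetic Renyi entropy (no log-space tricks)."""
    p = np.asarray(p, dtype=float)
    return float(np.log2(np.sum(p**beta)) / (1.0 - beta))


def finite_difference_gradient(values: np.ndarray):
    """Explicit loop-based central/one-sided differencing."""
    h, w = values.shape
    gx = np.empty_like(values)
    gy = np.empty_like(values)
    for y in range(h):
        for x in range(w):
            if 0 < x < w - 1:
                gx[y, x] = (values[y, x + 1] - values[y, x - 1]) / 2.0
            elif x == 0:
                gx[y, x] = values[y, 1] - values[y, 0]
            else:
                gx[y, x] = values[y, w - 1] - values[y, w - 2]
            if 0 < y < h - 1:
                gy[y, x] = (values[y + 1, x] - values[y - 1, x]) / 2.0
            elif y == 0:
                gy[y, x] = values[1, x] - values[0, x]
            else:
                gy[y, x] = values[h - 1, x] - values[h - 2, x]
    return gx, gy


def histogram_bin_oracle(thetas, bin_count: int) -> np.ndarray:
    """Independent binning: np.histogram over [-90, 90) edges."""
    edges = np.linspace(-90.0, 90.0, bin_count + 1)
    idx = np.digitize(np.asarray(thetas, dtype=float), edges) - 1
    return np.clip(idx, 0, bin_count - 1)


def antipodal_dp_oracle(n: int) -> list[tuple[int, int]]:
    """Exhaustive minimizer over all maximal pairings of n frames.

    Minimizes total |angular separation - 180| over matchings of size
    floor(n/2); among minimizers returns the lexicographically smallest
    sorted pair list.  Bitmask DP == exhaustive search for n <= 20.
    """
    def dev(i, j):
        sep = min(abs(i - j), n - abs(i - j)) * 360.0 / n
        return abs(sep - 180.0)

    size_target = n // 2
    full = (1 << n) - 1
    memo: dict[tuple[int, int], tuple[float, tuple]] = {}

    def best(mask: int, remaining_pairs: int) -> tuple[float, tuple]:
        if remaining_pairs == 0:
            return 0.0, ()
        key = (mask, remaining_pairs)
        if key in memo:
            return memo[key]
        # lowest unused frame must either pair now or stay unpaired
        i = 0
        while mask >> i & 1:
            i += 1
        options = []
        for j in range(i + 1, n):
            if not mask >> j & 1:
                cost, rest = best(mask | 1 << i | 1 << j, remaining_pairs - 1)
                options.append((dev(i, j) + cost, ((i, j),) + rest))
        # skip frame i entirely (only legal if enough frames remain)
        free = n - bin(mask).count("1")
        if free - 1 >= 2 * remaining_pairs:
            cost, rest = best(mask | 1 << i, remaining_pairs)
            options.append((cost, rest))
        res = min(options, key=lambda t: (round(t[0], 9), t[1]))
        memo[key] = res
        return res

    _, pairs = best(0, size_target)
    return sorted(pairs)
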