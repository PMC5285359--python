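"""Bounded Voronoi tessellation, edge-sharing adjacency, nucleus clusters.

A Voronoi region V(s) is the set of points of the image rectangle nearer
to its generating point s than to any other generator (Euclidean metric).
Regions of a finite image must themselves be finite, so every unbounded
cell is clipped to the rectangle.  The clipping is performed exactly by
the reflection construction: the generator set is mirrored across each of
the four boundary lines before the diagram is computed, which makes the
perpendicular bisector between a point and its mirror coincide with the
boundary itself — the cells of the original generators are then precisely
the clipped cells, with no polygon-intersection step.

Two regions are *strongly near* (adjacent) when they share a boundary edge
of positive length; meeting at a single vertex does not count.  A nucleus
cluster is a region together with all regions adjacent to it, and a
maximal nucleus cluster (MNC) is one whose nucleus has the greatest
adjacency degree in the tiling.  Degree ties are real (images frequently
carry several MNCs) and all tied clusters are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from .seeding import GeneratingPointSet

__all__ = [
    "VoronoiTiling",
    "NucleusCluster",
    "DuplicatePoints",
    "AllCollinearPoints",
    "build_tessellation",
    "region_area",
    "region_adjacency",
    "nucleus_cluster",
    "find_maximal_nucleus_clusters",
]

#: minimum shared-boundary length for two regions to count as adjacent
EPS_EDGE = 1e-9
#: point-equality tolerance for all geometry predicates
EPS_GEOM = 1e-9


class DuplicatePoints(ValueError):
    """Two generating points coincide (within geometric tolerance)."""


class AllCollinearPoints(ValueError):
    """All generating points lie on one line: the diagram is degenerate."""


@dataclass(frozen=True)
class NucleusCluster:
    """A nucleus region with its strongly-near neighborhood."""

    nucleus_id: int
    adjacent_ids: frozenset[int]
    is_maximal: bool

    @property
    def degree(self) -> int:
        return len(self.adjacent_ids)

    @property
    def region_ids(self) -> frozenset[int]:
        """All region ids in the cluster: nucleus plus adjacent."""
        return self.adjacent_ids | {self.nucleus_id}


@dataclass(frozen=True)
class VoronoiTiling:
    """A bounded Voronoi tiling of an image rectangle.

    ``regions[i]`` is the convex polygon of generator i as an (k, 2) vertex
    array, counter-clockwise, starting at the lexicographically smallest
    vertex (bit-stable output).  ``adjacency[i]`` is the frozenset of ids
    sharing an edge (length > EPS_EDGE) with region i.
    """

    bounds: tuple[float, float]
    coords: np.ndarray
    regions: tuple[np.ndarray, ...]
    adjacency: tuple[frozenset[int], ...]
    point_set: GeneratingPointSet | None = field(default=None, compare=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=int)


def _as_coords(points) -> tuple[np.ndarray, GeneratingPointSet | None]:
    if isinstance(points, GeneratingPointSet):
        return points.coords(), points
    return np.asarray(points, dtype=float), None


def _canonical_polygon(verts: np.ndarray) -> np.ndarray:
    """Order convex-polygon vertices CCW starting at the smallest (x, y)."""
    center = verts.mean(axis=0)
    ang = np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0])
    verts = verts[np.argsort(ang, kind="stable")]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    return np.roll(verts, -start, axis=0)


def _dedupe_ring(verts: np.ndarray) -> np.ndarray:
    """Drop consecutive near-equal vertices (closed ring, tol EPS_GEOM)."""
    keep = []
    n = len(verts)
    for i in range(n):
        if np.linalg.norm(verts[i] - verts[(i - 1) % n]) > EPS_GEOM:
            keep.append(i)
    return verts[keep] if keep else verts[:1]


def build_tessellation(points, bounds: tuple[float, float]) -> VoronoiTiling:
    """Build the bounded Voronoi tiling of ``points`` in a rectangle.

    Parameters
    ----------
    points
        A GeneratingPointSet (pixel seeds are placed at pixel centers) or
        an (n, 2) array-like of (x, y) coordinates, all strictly inside
        the rectangle.
    bounds
        (width, height) of the rectangle [0, width] x [0, height].

    Raises
    ------
    DuplicatePoints, AllCollinearPoints, ValueError (out-of-bounds or
    fewer than 4 points).
    """
    coords, pset = _as_coords(points)
    w, h = float(bounds[0]), float(bounds[1])
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("points must be an (n, 2) coordinate array")
    n = len(coords)
    if n < 2:
        raise ValueError(f"need at least 2 generating points, got {n}")
    if np.any(coords[:, 0] <= 0) or np.any(coords[:, 0] >= w) or np.any(
        coords[:, 1] <= 0
    ) or np.any(coords[:, 1] >= h):
        raise ValueError("all generating points must lie strictly inside bounds")
    # duplicate check at geometric tolerance
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    sorted_c = coords[order]
    if np.any(np.linalg.norm(np.diff(sorted_c, axis=0), axis=1) <= EPS_GEOM):
        raise DuplicatePoints("two generating points coincide")
    centered = coords - coords.mean(axis=0)
    if n >= 3 and np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise AllCollinearPoints("generating points are collinear")

    # reflect across x=0, x=w, y=0, y=h: exact rectangle clipping
    refl = [coords]
    for flip in (
        lambda p: np.column_stack([-p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([2 * w - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], -p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * h - p[:, 1]]),
    ):
        refl.append(flip(coords))
    vor = Voronoi(np.vstack(refl))

    regions: list[np.ndarray] = []
    for i in range(n):
        verts_idx = vor.regions[vor.point_region[i]]
        if -1 in verts_idx or len(verts_idx) < 3:
            raise RuntimeError(f"region {i} is unbounded or degenerate")
        verts = _dedupe_ring(_canonical_polygon(vor.vertices[verts_idx]))
        # snap coordinates that landed within tolerance of the boundary
        verts[:, 0] = np.clip(verts[:, 0], 0.0, w)
        verts[:, 1] = np.clip(verts[:, 1], 0.0, h)
        regions.append(verts)

    adjacency: list[set[int]] = [set() for _ in range(n)]
    for (p, q), (va, vb) in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n or va < 0 or vb < 0:
            continue
        if np.linalg.norm(vor.vertices[va] - vor.vertices[vb]) > EPS_EDGE:
            adjacency[p].add(int(q))
            adjacency[q].add(int(p))

    return VoronoiTiling(
        bounds=(w, h),
        coords=coords,
        regions=tuple(regions),
        adjacency=tuple(frozenset(a) for a in adjacency),
        point_set=pset,
    )


def region_area(tiling: VoronoiTiling, region_id: int) -> float:
    """Shoelace area of a clipped region polygon, in square pixels."""
    verts = _get_region(tiling, region_id)
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def region_centroid(tiling: VoronoiTiling, region_id: int) -> tuple[float, float]:
    """Area centroid of a region polygon."""
    verts = _get_region(tiling, region_id)
    x, y = verts[:, 0], verts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return float(cx), float(cy)


def _get_region(tiling: VoronoiTiling, region_id: int) -> np.ndarray:
    if not 0 <= region_id < tiling.n_regions:
        raise KeyError(f"unknown region id {region_id}")
    return tiling.regions[region_id]


def region_adjacency(tiling: VoronoiTiling) -> tuple[frozenset[int], ...]:
    """The strongly-near relation: symmetric, irreflexive, edge-sharing."""
    return tiling.adjacency


def nucleus_cluster(tiling: VoronoiTiling, region_id: int) -> NucleusCluster:
    """The cluster with ``region_id`` as nucleus: itself plus all neighbors."""
    _get_region(tiling, region_id)
    adj = tiling.adjacency[region_id]
    max_deg = int(tiling.degrees().max())
    return NucleusCluster(
        nucleus_id=region_id, adjacent_ids=adj, is_maximal=len(adj) == max_deg
    )


def find_maximal_nucleus_clusters(tiling: VoronoiTiling) -> list[NucleusCluster]:
    """All clusters whose nucleus attains the maximum adjacency degree.

    Ties are returned together (multiple MNCs per image are common), in
    (y, x)-lexicographic nucleus order — which is region-id order, since
    generating points are stored (y, x)-sorted.
    """
    degs = tiling.degrees()
    max_deg = int(degs.max())
    ids = np.nonzero(degs == max_deg)[0]
    order = np.lexsort((tiling.coords[ids, 0], tiling.coords[ids, 1]))
    return [
        NucleusCluster(
            nucleus_id=int(i), adjacent_ids=tiling.adjacency[i], is_maximal=True
        )
        for i in ids[order]
    ]
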