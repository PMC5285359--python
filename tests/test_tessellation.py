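"""Bounded Voronoi tiling, adjacency and nucleus-cluster tests."""

from __future__ import annotations

import numpy as np
import pytest

import mnctess as M
from oracles import (
    adjacency_oracle,
    dilation_adjacency_oracle,
    membership_labels,
    nearest_label_oracle,
    raster_area_oracle,
)


def corner_square_tiling():
    """4 points at the corners of a centered square in a 10x10 box:
    the four bisectors meet at one point, a degenerate-contact case."""
    pts = [(2.5, 2.5), (7.5, 2.5), (2.5, 7.5), (7.5, 7.5)]
    return M.build_tessellation(pts, (10.0, 10.0))


class TestBuildTessellation:
    def test_two_point_bisector_split(self, two_point_tiling):
        areas = [M.region_area(two_point_tiling, i) for i in (0, 1)]
        np.testing.assert_allclose(areas, [50.0, 50.0], atol=1e-9)
        # split is the vertical line x=5
        assert all(two_point_tiling.regions[0][:, 0] <= 5.0 + 1e-9)
        assert all(two_point_tiling.regions[1][:, 0] >= 5.0 - 1e-9)

    def test_four_corner_squares(self):
        t = corner_square_tiling()
        for i in range(4):
            assert M.region_area(t, i) == pytest.approx(25.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(M.DuplicatePoints):
            M.build_tessellation([(1, 1), (1, 1), (3, 3), (4, 2)], (10, 10))
        with pytest.raises(M.AllCollinearPoints):
            M.build_tessellation([(1, 1), (2, 2), (3, 3), (4, 4)], (10, 10))
        with pytest.raises(ValueError):
            M.build_tessellation([(1, 1), (20, 2), (3, 3), (4, 4)], (10, 10))

    def test_regions_contain_generators_and_are_convex(self, seeded_instances):
        from shapely.geometry import Point, Polygon

        t = M.build_tessellation(seeded_instances[0], (64.0, 64.0))
        for i, verts in enumerate(t.regions):
            poly = Polygon(verts)
            assert poly.covers(Point(t.coords[i]))
            # convexity: CCW vertex walk never turns clockwise
            v = np.vstack([verts, verts[:2]])
            e = np.diff(v, axis=0)
            cross = e[:-1, 0] * e[1:, 1] - e[:-1, 1] * e[1:, 0]
            assert (cross >= -1e-9).all()

    def test_vertices_ccw_from_lexicographic_smallest(self, grid_tiling):
        for verts in grid_tiling.regions:
            keys = [(x, y) for x, y in verts]
            assert keys[0] == min(keys)
            area2 = np.sum(
                verts[:, 0] * np.roll(verts[:, 1], -1)
                - verts[:, 1] * np.roll(verts[:, 0], -1)
            )
            assert area2 > 0  # counter-clockwise

    def test_partition_of_bounds(self, seeded_instances):
        for s in (0, 7, 23):
            t = M.build_tessellation(seeded_instances[s], (64.0, 64.0))
            total = sum(M.region_area(t, i) for i in range(t.n_regions))
            assert total == pytest.approx(64.0 * 64.0, rel=1e-6)

    def test_nearest_point_membership(self, seeded_instances):
        pts = seeded_instances[1]
        t = M.build_tessellation(pts, (64.0, 64.0))
        labels, decided = nearest_label_oracle(pts, 64, 64)
        member = membership_labels(t)
        agree = (member[decided] == labels[decided]).mean()
        assert agree >= 0.995


class TestRegionArea:
    def test_unknown_id(self, grid_tiling):
        with pytest.raises(KeyError):
            M.region_area(grid_tiling, 99)

    def test_matches_raster_oracle(self, seeded_instances):
        """Pixel-counting rasterization agrees with the shoelace area up
        to boundary quantization: the miscounted pixels straddle the
        region boundary, so the error is bounded by a fraction of the
        perimeter (2% relative holds for regions large relative to it)."""
        for s in (2, 11, 29):
            t = M.build_tessellation(seeded_instances[s], (64.0, 64.0))
            raster = raster_area_oracle(t)
            for i in range(t.n_regions):
                verts = np.vstack([t.regions[i], t.regions[i][:1]])
                perim = np.linalg.norm(np.diff(verts, axis=0), axis=1).sum()
                area = M.region_area(t, i)
                tol = max(0.02 * area, 0.5 * perim)
                assert abs(area - raster[i]) <= tol


class TestAdjacency:
    def test_two_point_adjacent(self, two_point_tiling):
        assert two_point_tiling.adjacency[0] == frozenset({1})

    def test_four_corner_no_diagonal_adjacency(self):
        t = corner_square_tiling()
        # ids are in (y, x) input order: 0=(2.5,2.5) 1=(7.5,2.5)
        #                                2=(2.5,7.5) 3=(7.5,7.5)
        assert 3 not in t.adjacency[0] and 0 not in t.adjacency[3]
        assert 2 not in t.adjacency[1] and 1 not in t.adjacency[2]
        assert t.adjacency[0] == frozenset({1, 2})

    def test_symmetric_irreflexive(self, seeded_instances):
        t = M.build_tessellation(seeded_instances[3], (64.0, 64.0))
        for i, adj in enumerate(t.adjacency):
            assert i not in adj
            for j in adj:
                assert i in t.adjacency[j]

    def test_equals_exhaustive_polygon_oracle(self, seeded_instances):
        for s in (4, 17, 33):
            t = M.build_tessellation(seeded_instances[s], (64.0, 64.0))
            assert list(t.adjacency) == adjacency_oracle(t)

    def test_consistent_with_raster_dilation(self, seeded_instances):
        """Adjacency agrees with the rasterized-label dilation oracle up
        to pixel resolution: every robustly shared raster boundary is a
        true edge, and every shared edge longer than 2 px shows up in the
        raster."""
        from shapely.geometry import Polygon

        t = M.build_tessellation(seeded_instances[5], (64.0, 64.0))
        raster_pairs = dilation_adjacency_oracle(t)
        true_pairs = {
            (i, j) for i, a in enumerate(t.adjacency) for j in a if i < j
        }
        polys = [Polygon(v) for v in t.regions]
        for i, j in true_pairs:
            if polys[i].intersection(polys[j]).length > 2.0:
                assert (i, j) in raster_pairs
        # conversely, raster contact is real adjacency unless the shared
        # edge is too short to rasterize reliably
        assert raster_pairs <= true_pairs | {
            p for p in raster_pairs
            if polys[p[0]].intersection(polys[p[1]]).length <= 2.0
        }


class TestNucleusClusters:
    def test_two_point_degrees(self, two_point_tiling):
        c = M.nucleus_cluster(two_point_tiling, 0)
        assert c.degree == 1 and c.is_maximal

    def test_grid_center_has_degree_four(self, grid_tiling):
        # region 4 is the center of the 3x3 grid
        c = M.nucleus_cluster(grid_tiling, 4)
        assert c.degree == 4
        assert c.adjacent_ids == frozenset({1, 3, 5, 7})
        mncs = M.find_maximal_nucleus_clusters(grid_tiling)
        assert [m.nucleus_id for m in mncs] == [4]

    def test_two_point_tie_returns_both(self, two_point_tiling):
        mncs = M.find_maximal_nucleus_clusters(two_point_tiling)
        assert [m.nucleus_id for m in mncs] == [0, 1]

    def test_degrees_match_oracle_and_argmax(self, seeded_instances):
        t = M.build_tessellation(seeded_instances[6], (64.0, 64.0))
        oracle = adjacency_oracle(t)
        for i in range(t.n_regions):
            assert M.nucleus_cluster(t, i).degree == len(oracle[i])
        max_deg = max(len(a) for a in oracle)
        expected = [i for i in range(t.n_regions) if len(oracle[i]) == max_deg]
        got = [m.nucleus_id for m in M.find_maximal_nucleus_clusters(t)]
        assert sorted(got) == expected
        assert all(m.degree == max_deg for m in
                   M.find_maximal_nucleus_clusters(t))
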