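import numpy as np
import pytest

from trabnet.graph import deduplicate
from trabnet.skeleton import (bridge_gaps, build_spatial_graph,
                              merge_close_nodes, prune_spurs, radius_map,
                              skeletonize, smooth_polylines, weld_pass_through)
from trabnet.volume import BinaryVolume


def neighbor_count(mask):
    """26-neighbor counts for every skeleton voxel (classification oracle)."""
    vox = {tuple(v) for v in np.argwhere(mask)}
    counts = {}
    for v in vox:
        c = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    if (v[0] + dz, v[1] + dy, v[2] + dx) in vox:
                        c += 1
        counts[v] = c
    return counts


def voxel_graph_cycle_rank(mask):
    """Cycle rank of the 26-connectivity voxel graph (networkx oracle)."""
    import networkx as nx
    G = nx.Graph()
    vox = [tuple(v) for v in np.argwhere(mask)]
    G.add_nodes_from(vox)
    s = set(vox)
    for v in vox:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    w = (v[0] + dz, v[1] + dy, v[2] + dx)
                    if w != v and w in s:
                        G.add_edge(v, w)
    return len(G.edges) - len(G.nodes) + nx.number_connected_components(G)


class TestSkeletonize:
    def test_cylinder_centerline(self, cylinder_mask):
        skel = skeletonize(cylinder_mask)
        assert not (skel.mask & ~cylinder_mask.mask).any()
        counts = neighbor_count(skel.mask)
        endpoints = [v for v, c in counts.items() if c == 1]
        junctions = [v for v, c in counts.items() if c >= 3]
        assert len(endpoints) == 2
        assert junctions == []

    def test_torus_keeps_one_cycle(self, torus_mask):
        skel = skeletonize(torus_mask)
        assert voxel_graph_cycle_rank(skel.mask) == 1

    def test_single_voxel_survives(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        skel = skeletonize(BinaryVolume(m, 3.0))
        np.testing.assert_array_equal(skel.mask, m)

    def test_component_count_preserved(self, rng):
        from scipy import ndimage
        zz, yy, xx = np.mgrid[0:20, 0:20, 0:20]
        rod1 = (np.hypot(xx - 4.0, zz - 4.0) <= 2.5) & (yy >= 2) & (yy < 18)
        rod2 = (np.hypot(xx - 14.0, zz - 14.0) <= 2.5) & (yy >= 2) & (yy < 18)
        m = rod1 | rod2
        bv = BinaryVolume(m, 3.0)
        skel = skeletonize(bv)
        _, n_in = ndimage.label(m, ndimage.generate_binary_structure(3, 3))
        _, n_out = ndimage.label(skel.mask,
                                 ndimage.generate_binary_structure(3, 3))
        assert n_in == n_out == 2

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(BinaryVolume(np.zeros((4, 4, 4), dtype=bool), 3.0))


class TestRadiusMap:
    def brute_force_radius(self, mask, h, voxel):
        """Distance to the nearest background voxel center (µm)."""
        bg = np.argwhere(~mask)
        d = np.linalg.norm((bg - np.array(voxel)) * h, axis=1)
        return d.min()

    def test_ball_center_radius(self):
        zz, yy, xx = np.mgrid[0:13, 0:13, 0:13]
        ball = np.sqrt((zz - 6.0) ** 2 + (yy - 6.0) ** 2 + (xx - 6.0) ** 2) <= 5.0
        bv = BinaryVolume(ball, 3.0)
        r = radius_map(bv, correction="center")
        assert abs(r[6, 6, 6] - 5.0 * 3.0) <= 3.0
        oracle = self.brute_force_radius(ball, 3.0, (6, 6, 6))
        assert r[6, 6, 6] == pytest.approx(oracle - 1.5)

    def test_single_voxel_floor(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        r = radius_map(BinaryVolume(m, 3.0), correction="center")
        assert r[2, 2, 2] == pytest.approx(1.5)
        assert (r[~m] == 0).all()

    def test_all_foreground_grows_to_center(self):
        # the volume faces act as the boundary: maximum at the center
        m = np.ones((9, 9, 9), dtype=bool)
        r = radius_map(BinaryVolume(m, 3.0), correction="none")
        assert r[4, 4, 4] == r.max()
        assert r[0, 0, 0] < r[4, 4, 4]
        assert r[4, 4, 4] == pytest.approx(5.0 * 3.0)  # 5 voxels to outside

    def test_matches_brute_force_on_random_mask(self, rng):
        m = rng.random((8, 8, 8)) < 0.5
        m[0, 0, 0] = False
        bv = BinaryVolume(m, 2.0)
        r = radius_map(bv, correction="none")
        padded = np.pad(m, 1, constant_values=False)
        for voxel in [tuple(v) for v in np.argwhere(m)][:20]:
            pv = tuple(np.array(voxel) + 1)
            assert r[voxel] == pytest.approx(
                self.brute_force_radius(padded, 2.0, pv))


class TestBuildSpatialGraph:
    def test_cylinder_two_nodes_one_segment(self, cylinder_mask):
        skel = skeletonize(cylinder_mask)
        g = build_spatial_graph(skel, radius_map(cylinder_mask))
        assert g.n_nodes == 2
        assert g.n_segments == 1
        from trabnet.descriptors import curved_length
        # hand-traced: 16 path voxels -> 15 steps of 3 µm
        assert curved_length(g.segments[0]) == pytest.approx(45.0)

    def test_plus_fixture(self, plus_mask):
        g = build_spatial_graph(plus_mask)
        assert g.n_nodes == 5
        assert g.n_segments == 4
        assert sorted(g.valence(n) for n in g.nodes) == [1, 1, 1, 1, 4]

    def test_torus_cycle_rank_one(self, torus_mask):
        skel = skeletonize(torus_mask)
        g = build_spatial_graph(skel, radius_map(torus_mask))
        rank = g.n_segments - g.n_nodes + 1
        assert rank == 1
        assert g.segments[0].is_loop

    def test_adjacency_conservation(self, plus_mask):
        # every skeleton path adjacency is consumed exactly once:
        # 4 arms x 4 path voxels + center = polyline points add up
        g = build_spatial_graph(plus_mask)
        total_steps = sum(len(s.points) - 1 for s in g.segments)
        assert total_steps == 16  # 4 arms x 4 inter-voxel steps

    def test_point_radii_from_field(self, cylinder_mask):
        skel = skeletonize(cylinder_mask)
        r = radius_map(cylinder_mask)
        g = build_spatial_graph(skel, r)
        seg = g.segments[0]
        assert seg.radii is not None
        assert (seg.radii > 0).all()
        # mid-segment radius close to the cylinder radius (4 vox = 12 µm)
        mid = seg.radii[len(seg.radii) // 2]
        assert mid == pytest.approx(12.0, abs=3.0)


class TestCleaning:
    def test_prune_spurs_removes_short_twigs(self):
        from conftest import star_graph
        g, c = star_graph([(1, 0, 0), (0, 1, 0), (-1, 0, 0)], length=20.0)
        tip = g.add_node((0.0, 0.0, 2.0), 1.5)
        g.add_segment(c, tip, np.array([[0, 0, 0], [0, 0, 2.0]]),
                      np.full(2, 1.5))
        assert g.valence(c) == 4
        prune_spurs(g, min_length=5.0)
        assert g.valence(c) == 3
        assert tip not in g.nodes

    def test_prune_interior_free_ends_keeps_boundary(self):
        from conftest import star_graph
        g, c = star_graph([(1, 0, 0), (0, 1, 0)], length=28.0,
                          center=(30.0, 30.0, 30.0))
        # long interior twig (would survive the length rule alone)
        tip = g.add_node((30.0, 30.0, 45.0), 1.5)
        g.add_segment(c, tip, np.array([[30, 30, 30], [30, 30, 45.0]]),
                      np.full(2, 1.5))
        bounds = (np.zeros(3), np.full(3, 60.0))
        prune_spurs(g, min_length=5.0, bounds=bounds, boundary_margin=6.0)
        assert tip not in g.nodes          # interior free end: artifact
        assert g.n_segments == 2           # boundary-reaching arms survive

    def test_weld_pass_through(self):
        from trabnet.graph import SpatialGraph
        g = SpatialGraph()
        a = g.add_node((0, 0, 0), 1.0)
        m = g.add_node((5, 0, 0), 1.0)
        b = g.add_node((10, 0, 0), 1.0)
        g.add_segment(a, m, np.array([[0, 0, 0], [5, 0, 0.0]]), np.ones(2))
        g.add_segment(m, b, np.array([[5, 0, 0], [10, 0, 0.0]]), np.ones(2))
        weld_pass_through(g)
        assert g.n_segments == 1
        assert m not in g.nodes
        assert len(g.segments[0].points) == 3

    def test_merge_close_nodes(self):
        from trabnet.graph import SpatialGraph
        g = SpatialGraph()
        a = g.add_node((0, 0, 0), 1.0)
        b = g.add_node((1.0, 0, 0), 1.0)
        c = g.add_node((20, 0, 0), 1.0)
        g.add_segment(a, c, np.array([[0, 0, 0], [20, 0, 0.0]]), np.ones(2))
        g.add_segment(b, c, np.array([[1.0, 0, 0], [20, 0, 0.0]]), np.ones(2))
        merge_close_nodes(g, radius=2.0)
        assert g.n_nodes == 2
        assert g.valence(a) == 2

    def test_bridge_gaps_rejoins_facing_tips(self):
        from trabnet.graph import SpatialGraph
        g = SpatialGraph()
        a = g.add_node((0, 0, 0), 1.0)
        t1 = g.add_node((9, 0, 0), 1.0)
        t2 = g.add_node((11, 0, 0), 1.0)
        b = g.add_node((20, 0, 0), 1.0)
        g.add_segment(a, t1, np.array([[0, 0, 0], [5, 0, 0], [9, 0, 0.0]]),
                      np.ones(3))
        g.add_segment(t2, b, np.array([[11, 0, 0], [15, 0, 0], [20, 0, 0.0]]),
                      np.ones(3))
        bridge_gaps(g, max_gap=3.0)
        assert g.n_segments == 1
        assert g.n_nodes == 2
        from trabnet.descriptors import chord_length
        assert chord_length(g.segments[0]) == pytest.approx(20.0)

    def test_smoothing_reduces_staircase_length(self, rng):
        from trabnet.graph import SpatialGraph
        from trabnet.descriptors import curved_length
        g = SpatialGraph()
        a = g.add_node((0, 0, 0))
        n = 21
        t = np.arange(n, dtype=float)
        pts = np.column_stack([t, (t % 2), np.zeros(n)])  # zigzag
        pts[-1, 1] = 0.0
        b = g.add_node(pts[-1])
        g.add_segment(a, b, pts)
        before = curved_length(g.segments[0])
        smooth_polylines(g, iterations=3)
        after = curved_length(g.segments[0])
        assert after < before
        np.testing.assert_allclose(g.segments[0].points[0], [0, 0, 0])
        np.testing.assert_allclose(g.segments[0].points[-1], pts[-1])
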