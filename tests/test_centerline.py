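import math

import numpy as np
import pytest

from conftest import circle_points
from fibremorph.centerline import (
    FibrePath,
    build_graph,
    prune_spurs,
    refine_centerline,
    resample_arclength,
    skeletonize,
    smooth_path,
)
from fibremorph.phantoms import (
    CircularArc,
    Segment,
    TreeSpec,
    TubeSpec,
    rasterize_tree,
    rasterize_tube,
)
from fibremorph.segmentation import BinaryMask
from scipy import ndimage


class TestSkeletonize:
    def test_straight_tube_close_to_axis(self, straight_tube):
        mask, _ = straight_tube
        skel, iso = skeletonize(mask)
        vox = np.argwhere(skel)
        # axis runs along x at y=z=10; Hausdorff distance <= 1 voxel
        d = np.sqrt((vox[:, 0] - 10) ** 2 + (vox[:, 1] - 10) ** 2)
        assert d.max() <= 1.0 + 1e-9

    def test_sphere_collapses_to_centre(self):
        from skimage.morphology import ball

        mask = BinaryMask(np.pad(ball(8), 2), (1, 1, 1))
        skel, _ = skeletonize(mask)
        vox = np.argwhere(skel)
        d = np.linalg.norm(vox - 10, axis=1)
        assert d.max() <= 4.0  # within r/2 of the centre

    def test_single_voxel(self):
        vox = np.zeros((5, 5, 5), dtype=bool)
        vox[2, 2, 2] = True
        skel, _ = skeletonize(BinaryMask(vox, (1, 1, 1)))
        assert skel.sum() == 1 and skel[2, 2, 2]

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            skeletonize(BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))

    def test_topology_preserved(self, straight_tube):
        mask, _ = straight_tube
        two = np.concatenate([mask.voxels, mask.voxels], axis=0)
        skel, _ = skeletonize(BinaryMask(two, mask.spacing))
        s = np.ones((3, 3, 3))
        _, n_mask = ndimage.label(two, structure=s)
        _, n_skel = ndimage.label(skel, structure=s)
        assert n_mask == n_skel == 2

    def test_anisotropic_resampled_to_isotropic(self):
        spec = TubeSpec(Segment((5, 10, 10), (45, 10, 10)), 3.0)
        mask, _ = rasterize_tube(spec, (40, 20, 52), (0.5, 1.0, 1.0))
        skel, iso = skeletonize(mask)
        assert iso == 0.5


class TestBuildGraph:
    def test_straight_tube_graph(self, straight_tube):
        mask, _ = straight_tube
        skel, iso = skeletonize(mask)
        g = build_graph(skel, iso)
        assert len(g.endpoints) == 2
        assert len(g.junctions) == 0
        assert g.n_edges == 1

    def test_y_tree_graph(self):
        nodes = [(10, 10, 10), (25, 25, 10), (40, 12, 10), (40, 38, 12)]
        mask, _ = rasterize_tree(
            TreeSpec(nodes, [-1, 0, 1, 1], [0, 2, 2, 2]), (24, 50, 52), (1, 1, 1)
        )
        skel, iso = skeletonize(mask)
        g = prune_spurs(build_graph(skel, iso))
        assert len(g.endpoints) == 3
        assert len(g.junctions) == 1
        assert g.n_edges == 3

    def test_torus_cycle_with_anchor(self):
        arc = CircularArc(centre=(20, 20, 12), radius=12.0, span=2 * math.pi)
        mask, _ = rasterize_tube(TubeSpec(arc, 2.5), (24, 40, 40), (1, 1, 1))
        skel, iso = skeletonize(mask)
        g = build_graph(skel, iso)
        assert len(g.endpoints) == 0
        assert len(g.junctions) == 0
        assert g.n_edges == 1
        assert len(g.nodes_of_kind("isolated")) == 1

    def test_handshake_identity(self, quarter_arc_tube):
        mask, _, _ = quarter_arc_tube
        skel, iso = skeletonize(mask)
        g = build_graph(skel, iso)
        degree_sum = sum(d for _, d in g.graph.degree())
        assert degree_sum == 2 * g.n_edges

    def test_polyline_steps_and_membership(self, quarter_arc_tube):
        mask, _, _ = quarter_arc_tube
        skel, iso = skeletonize(mask)
        g = build_graph(skel, iso)
        diag = math.sqrt(3) * iso
        for _, _, _, poly in g.edge_polylines():
            assert len(poly) >= 2
            steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            assert steps.max() <= diag + 1e-9
            idx = np.round(poly[:, ::-1] / iso).astype(int)  # (x,y,z)->(z,y,x)
            assert mask.voxels[tuple(idx.T)].all()

    def test_edge_lengths_match_polylines(self, quarter_arc_tube):
        mask, _, _ = quarter_arc_tube
        skel, iso = skeletonize(mask)
        g = build_graph(skel, iso)
        for u, v, k, poly in g.edge_polylines():
            stored = g.graph.edges[u, v, k]["length"]
            assert stored == pytest.approx(
                np.linalg.norm(np.diff(poly, axis=0), axis=1).sum(), abs=1e-9
            )

    def test_skeleton_of_connected_mask_is_connected(self, quarter_arc_tube):
        mask, _, _ = quarter_arc_tube
        skel, _ = skeletonize(mask)
        _, n = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestRotationInvariance:
    def test_graph_metrics_under_90deg_rotation(self, quarter_arc_tube):
        mask, _, _ = quarter_arc_tube
        results = []
        vox = mask.voxels
        for k in range(2):
            m = BinaryMask(np.rot90(vox, k=k, axes=(1, 2)).copy(), mask.spacing)
            skel, iso = skeletonize(m)
            g = prune_spurs(build_graph(skel, iso))
            results.append((len(g.endpoints), len(g.junctions), g.total_length()))
        assert results[0][0] == results[1][0]
        assert results[0][1] == results[1][1]
        assert results[0][2] == pytest.approx(results[1][2], rel=0.02)


class TestRefine:
    def _tube_graph(self, mask):
        skel, iso = skeletonize(mask)
        return prune_spurs(build_graph(skel, iso))

    def test_displaced_path_pulled_to_axis(self, straight_tube):
        mask, _ = straight_tube
        g = self._tube_graph(mask)
        # displace interior points one voxel off-axis
        for u, v, k, poly in g.edge_polylines():
            poly[1:-1, 1] += 1.0
            g.graph.edges[u, v, k]["polyline"] = poly
        rms_before = self._rms_to_axis(g)
        refined = refine_centerline(g, mask, iterations=2)
        rms_after = self._rms_to_axis(refined)
        assert rms_after <= rms_before
        assert rms_after <= 0.5

    @staticmethod
    def _rms_to_axis(g):
        devs = []
        for _, _, _, poly in g.edge_polylines():
            devs.append((poly[1:-1, 1] - 10) ** 2 + (poly[1:-1, 2] - 10) ** 2)
        return math.sqrt(np.concatenate(devs).mean())

    def test_centred_path_is_fixed_point(self, straight_tube):
        mask, _ = straight_tube
        g = self._tube_graph(mask)
        refined = refine_centerline(g, mask, iterations=2)
        for (_, _, _, p0), (_, _, _, p1) in zip(
            g.edge_polylines(), refined.edge_polylines()
        ):
            assert np.allclose(p0, p1, atol=1e-6)

    def test_arc_refined_close_to_axis(self, quarter_arc_tube):
        mask, _, arc = quarter_arc_tube
        g = self._tube_graph(mask)
        refined = refine_centerline(g, mask, iterations=2)
        centre = np.array([10.0, 15.0, 10.0])
        devs = []
        for _, _, _, poly in refined.edge_polylines():
            d = poly[1:-1] - centre
            rad = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
            devs.append((rad - 20.0) ** 2 + d[:, 2] ** 2)
        assert math.sqrt(np.concatenate(devs).mean()) <= 0.5

    def test_node_positions_fixed_by_default(self, straight_tube):
        mask, _ = straight_tube
        g = self._tube_graph(mask)
        before = {n: d["position"].copy() for n, d in g.graph.nodes(data=True)}
        refined = refine_centerline(g, mask, iterations=2)
        for n, d in refined.graph.nodes(data=True):
            assert np.allclose(d["position"], before[n])


class TestResample:
    def test_straight_segment(self):
        poly = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        path = resample_arclength(poly, 1.0)
        assert len(path) == 11
        steps = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        assert np.allclose(steps, 1.0)

    def test_fractional_tail(self):
        poly = np.array([[0, 0, 0], [10.4, 0, 0]], dtype=float)
        path = resample_arclength(poly, 1.0)
        assert len(path) == 12
        last = np.linalg.norm(path.points[-1] - path.points[-2])
        assert last == pytest.approx(0.4, abs=1e-9)

    def test_endpoints_preserved(self):
        poly = np.array([[1, 2, 3], [4, 6, 3], [8, 6, 6]], dtype=float)
        path = resample_arclength(poly, 1.0)
        assert np.allclose(path.points[0], poly[0])
        assert np.allclose(path.points[-1], poly[-1])

    def test_circle_resampled_stays_on_circle(self):
        dense = circle_points(10.0, 0.05)
        path = resample_arclength(dense, 1.0)
        r = np.linalg.norm(path.points[:, :2], axis=1)
        assert np.abs(r - 10.0).max() <= 0.05

    def test_degenerate_polyline_errors(self):
        with pytest.raises(ValueError):
            resample_arclength(np.zeros((2, 3)), 1.0)


class TestSmoothPath:
    def test_window_one_identity(self):
        path = FibrePath(circle_points(10.0, 1.0, 20))
        out = smooth_path(path, 1)
        assert np.allclose(out.points, path.points)

    def test_collinear_unchanged(self):
        pts = np.stack([np.arange(20.0), np.zeros(20), np.zeros(20)], axis=1)
        out = smooth_path(FibrePath(pts), 5)
        assert np.allclose(out.points, pts, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_path(FibrePath(circle_points(10.0, 1.0, 10)), 4)

    def test_jittered_circle_rms_reduced(self):
        improved = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = circle_points(10.0, 1.0, 40)
            noisy = pts + rng.normal(0, 0.2, pts.shape)
            sm = smooth_path(FibrePath(noisy), 5).points

            def rms(q):
                r = np.linalg.norm(q[:, :2], axis=1)
                return math.sqrt(np.mean((r - 10.0) ** 2 + q[:, 2] ** 2))

            if rms(sm) < rms(noisy):
                improved += 1
        assert improved == 10
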