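"""Vascular descriptors: lengths, diameters, SOAM, CLR, Betti numbers, volume."""

import numpy as np
import pytest

from vasoquant.descriptors import (
    betti_numbers,
    branch_statistics,
    clr,
    describe,
    skeleton_blood_volume,
    soam,
)
from vasoquant.pipeline_io import make_single_tube_network
from vasoquant.vascgen import Branch, VesselNetwork

from conftest import STRING_VOLUME_MM3


def soam_bruteforce(points):
    """Second, fully explicit implementation of the sum-of-angles measure."""
    pts = np.asarray(points, float)
    t = [pts[i + 1] - pts[i] for i in range(len(pts) - 1)]
    t = [v for v in t if np.linalg.norm(v) > 0]
    total = 0.0
    for k in range(len(t) - 1):
        u1 = t[k] / np.linalg.norm(t[k])
        u2 = t[k + 1] / np.linalg.norm(t[k + 1])
        ip = np.arccos(np.clip(u1 @ u2, -1, 1))
        tp = 0.0
        if k + 2 < len(t) + 0 and k + 2 <= len(t) - 1:
            u3 = t[k + 2] / np.linalg.norm(t[k + 2])
            b1, b2 = np.cross(u1, u2), np.cross(u2, u3)
            if np.linalg.norm(b1) > 1e-9 and np.linalg.norm(b2) > 1e-9:
                b1, b2 = b1 / np.linalg.norm(b1), b2 / np.linalg.norm(b2)
                tp = np.arccos(np.clip(b1 @ b2, -1, 1))
        total += np.sqrt(ip**2 + tp**2)
    length = sum(np.linalg.norm(v) for v in t)
    return total / length


def _graph_of(branches):
    nodes = {}
    for b in branches:
        nodes[b.start_node] = b.points[0]
        nodes[b.end_node] = b.points[-1]
    return VesselNetwork(nodes, branches, ((0, 0, 0), (100, 100, 100)))


class TestBranchStatistics:
    def test_string_length_and_diameter(self):
        net = make_single_tube_network(radius_mm=0.063, length_mm=8.4)
        table = branch_statistics(net)
        assert table.loc[0, "length_mm"] == pytest.approx(8.4)
        assert table.loc[0, "diameter_mm"] == pytest.approx(0.126)

    def test_single_voxel_step(self):
        b = Branch(0, 0, 1, np.array([[0, 0, 0], [0.02, 0, 0]]), np.array([0.01, 0.01]))
        assert branch_statistics(_graph_of([b])).loc[0, "length_mm"] == pytest.approx(0.02)

    def test_circular_arc_length(self):
        theta = np.linspace(0, np.pi / 2, 200)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        b = Branch(0, 0, 1, pts, np.full(len(pts), 0.01))
        assert branch_statistics(_graph_of([b])).loc[0, "length_mm"] == pytest.approx(
            np.pi / 2, rel=1e-4
        )


class TestSoam:
    def test_straight_line_zero(self):
        pts = np.stack([np.linspace(0, 5, 20), np.zeros(20), np.zeros(20)], axis=1)
        assert soam(pts) == 0.0

    def test_planar_right_angle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert soam(pts) == pytest.approx((np.pi / 2) / 2.0)

    def test_helix_matches_bruteforce_oracle(self):
        t = np.linspace(0, 4 * np.pi, 60)
        pts = np.stack([np.cos(t), np.sin(t), 0.2 * t], axis=1)
        assert soam(pts) == pytest.approx(soam_bruteforce(pts), rel=1e-9)

    def test_in_plane_only_leq_full(self):
        t = np.linspace(0, 4 * np.pi, 40)
        pts = np.stack([np.cos(t), np.sin(t), 0.3 * t], axis=1)
        assert soam(pts, in_plane_only=True) <= soam(pts) + 1e-12

    def test_too_few_points_warns(self):
        with pytest.warns(UserWarning):
            assert soam(np.array([[0, 0, 0], [1, 0, 0.0]])) == 0.0


class TestClr:
    def test_straight(self):
        pts = np.stack([np.linspace(0, 3, 10), np.zeros(10), np.zeros(10)], axis=1)
        assert clr(pts) == pytest.approx(1.0)

    def test_semicircle(self):
        theta = np.linspace(0, np.pi, 400)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        assert clr(pts) == pytest.approx(2 / np.pi, rel=1e-4)

    def test_closed_loop_flagged(self):
        theta = np.linspace(0, 2 * np.pi, 200)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        with pytest.warns(UserWarning, match="closed"):
            assert clr(pts) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            clr(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError):
            clr(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))


class TestBetti:
    def test_tree_triangle_k4(self):
        import networkx as nx

        assert betti_numbers(nx.random_labeled_tree(20, seed=1)) == (1, 0)
        assert betti_numbers(nx.cycle_graph(3)) == (1, 1)
        assert betti_numbers(nx.complete_graph(4)) == (1, 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_euler_identity_against_cycle_basis_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(rng.integers(5, 30), rng.uniform(0.05, 0.3), seed=seed)
        b0, b1 = betti_numbers(g)
        assert b0 == nx.number_connected_components(g)
        assert b1 == sum(len(nx.cycle_basis(g.subgraph(c).copy()))
                         for c in nx.connected_components(g))


class TestBloodVolume:
    def test_single_tube(self):
        net = make_single_tube_network(radius_mm=0.063, length_mm=8.4)
        assert skeleton_blood_volume(net) == pytest.approx(STRING_VOLUME_MM3)

    def test_zero_radius_zero_volume(self):
        b = Branch(0, 0, 1, np.array([[0, 0, 0], [1, 0, 0.0]]), np.array([0.0, 0.0]))
        assert skeleton_blood_volume(_graph_of([b])) == 0.0

    def test_additivity_of_disjoint_tubes(self):
        one = make_single_tube_network()
        two_branches = [
            Branch(0, 0, 1, one.branches[0].points, one.branches[0].radii),
            Branch(1, 2, 3, one.branches[0].points + np.array([0, 2.0, 0]), one.branches[0].radii),
        ]
        nodes = {0: two_branches[0].points[0], 1: two_branches[0].points[-1],
                 2: two_branches[1].points[0], 3: two_branches[1].points[-1]}
        two = VesselNetwork(nodes, two_branches, one.domain_box)
        assert skeleton_blood_volume(two) == pytest.approx(2 * skeleton_blood_volume(one))

    def test_missing_radii_raise(self):
        b = Branch(0, 0, 1, np.array([[0, 0, 0], [1, 0, 0.0]]), np.array([0.01, 0.01]))
        b.radii = b.radii[:1]
        with pytest.raises(ValueError, match="radii"):
            skeleton_blood_volume(_graph_of([b]))


class TestInvariance:
    def test_rigid_motion_invariance_of_descriptors(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 0.2, (30, 3)), axis=0)
        radii = rng.uniform(0.02, 0.05, 30)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -40, 75], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 2.0])
        b1 = Branch(0, 0, 1, pts, radii)
        b2 = Branch(0, 0, 1, moved, radii)
        assert soam(moved) == pytest.approx(soam(pts), rel=1e-9)
        assert clr(moved) == pytest.approx(clr(pts), rel=1e-9)
        assert skeleton_blood_volume(_graph_of([b2])) == pytest.approx(
            skeleton_blood_volume(_graph_of([b1])), rel=1e-9
        )

    def test_describe_summary_consistency(self, binary_tree_network):
        ds = describe(binary_tree_network)
        assert ds["beta1"] == ds["n_edges"] - ds["n_nodes"] + ds["beta0"]
        assert ds.branch_table.shape[0] == ds["n_edges"] == 7
        assert (ds.branch_table["clr"] <= 1.0 + 1e-12).all()
        assert (ds.branch_table["soam_rad_per_mm"] >= 0).all()
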