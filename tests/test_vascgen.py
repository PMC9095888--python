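"""L-system network generation and rasterization."""

import numpy as np
import pytest

import vasoquant as vq
from vasoquant.descriptors import betti_numbers
from vasoquant.vascgen import (
    Branch,
    ConfigurationError,
    VesselNetwork,
    bresenham_line_3d,
    network_ground_truth_descriptors,
)
from vasoquant.volume import GridSpec

from conftest import STRING_VOLUME_MM3


def _single_segment_config(**kw):
    base = dict(
        axiom="F",
        productions=[],
        iterations=1,
        segment_length=(2.0, 0.0),
        root_position=(2.0, 2.0, 0.2),
        domain_box=((0.0, 0.0, 0.0), (4.0, 4.0, 4.0)),
    )
    base.update(kw)
    return vq.GrammarConfig(**base)


class TestGenerateLnet:
    def test_degenerate_single_segment(self):
        net = vq.generate_lnet(_single_segment_config())
        assert net.n_branches == 1
        assert net.branches[0].length_mm == pytest.approx(2.0)
        assert betti_numbers(net) == (1, 0)

    def test_binary_tree_rewriting(self, binary_tree_network):
        # F -> F[+F][-F] applied twice: trunk, two children, four grandchildren
        assert binary_tree_network.n_branches == 7
        assert betti_numbers(binary_tree_network) == (1, 0)

    def test_stochastic_geometry_deterministic_topology(self):
        def make(seed):
            return vq.generate_lnet(
                vq.GrammarConfig(
                    axiom="F",
                    productions=[("F", "F[+F][-F]", 1.0)],
                    iterations=3,
                    branch_angle_deg=(30.0, 6.0),
                    segment_length=(0.3, 0.0),
                    root_position=(3.0, 3.0, 0.2),
                    domain_box=((0.0, 0.0, 0.0), (6.0, 6.0, 6.0)),
                    rng_seed=seed,
                )
            )

        a, b = make(1), make(2)
        assert a.n_branches == b.n_branches
        pos_a = np.sort(np.vstack(list(a.nodes.values())), axis=0)
        pos_b = np.sort(np.vstack(list(b.nodes.values())), axis=0)
        assert not np.allclose(pos_a, pos_b)

    def test_seeded_determinism(self):
        cfg = vq.GrammarConfig(rng_seed=11)
        a, b = vq.generate_lnet(cfg), vq.generate_lnet(vq.GrammarConfig(rng_seed=11))
        assert a.n_branches == b.n_branches
        for ba, bb in zip(a.branches, b.branches):
            np.testing.assert_array_equal(ba.points, bb.points)
            np.testing.assert_array_equal(ba.radii, bb.radii)

    def test_invalid_probability_table(self):
        with pytest.raises(ConfigurationError, match="sum"):
            vq.generate_lnet(
                _single_segment_config(productions=[("F", "FF", 0.5), ("F", "F", 0.3)])
            )

    def test_network_stays_inside_domain_and_flags_clipping(self):
        cfg = _single_segment_config(
            segment_length=(10.0, 0.0), domain_box=((0.0, 0.0, 0.0), (4.0, 4.0, 4.0))
        )
        net = vq.generate_lnet(cfg)
        assert net.clipped_branches >= 1
        lo, hi = np.asarray(cfg.domain_box[0]), np.asarray(cfg.domain_box[1])
        for b in net.branches:
            assert np.all(b.points >= lo - 1e-9) and np.all(b.points <= hi + 1e-9)

    def test_child_radii_follow_murray_decay(self, binary_tree_network):
        radii = sorted({round(float(b.radii[0]), 6) for b in binary_tree_network.branches})
        r0 = 0.06
        f = 0.5 ** (1.0 / 3.0)
        assert radii == sorted(
            {round(r0, 6), round(r0 * f, 6), round(r0 * f * f, 6)}
        )

    def test_connectivity_of_generated_networks(self):
        for seed in range(3):
            net = vq.generate_lnet(vq.GrammarConfig(rng_seed=seed))
            assert betti_numbers(net)[0] == 1


class TestBresenham:
    def test_axis_aligned(self):
        line = bresenham_line_3d((2, 3, 4), (11, 3, 4))
        assert len(line) == 10
        assert np.all(line[:, 1] == 3) and np.all(line[:, 2] == 4)

    def test_space_diagonal(self):
        line = bresenham_line_3d((0, 0, 0), (5, 5, 5))
        np.testing.assert_array_equal(line, np.stack([np.arange(6)] * 3, axis=1))

    @pytest.mark.parametrize("seed", range(20))
    def test_chain_properties_random_endpoints(self, seed):
        rng = np.random.default_rng(seed)
        p0, p1 = rng.integers(-15, 15, 3), rng.integers(-15, 15, 3)
        line = bresenham_line_3d(p0, p1)
        assert len(line) == int(np.abs(p1 - p0).max()) + 1
        np.testing.assert_array_equal(line[0], p0)
        np.testing.assert_array_equal(line[-1], p1)
        steps = np.abs(np.diff(line, axis=0))
        assert steps.max(initial=0) <= 1  # 26-connected chain
        # independent oracle: same voxel count as skimage's nD line
        from skimage.draw import line_nd

        ours = len(line)
        theirs = len(line_nd(p0, p1, endpoint=True)[0])
        assert ours == theirs


class TestVoxelize:
    def test_axis_segment_thin_radius_gives_centerline_only(self):
        net = VesselNetwork(
            {0: np.array([0.0, 0.1, 0.1]), 1: np.array([0.18, 0.1, 0.1])},
            [
                Branch(
                    0,
                    0,
                    1,
                    np.array([[0.0, 0.1, 0.1], [0.18, 0.1, 0.1]]),
                    np.array([0.005, 0.005]),
                )
            ],
            ((0, 0, 0), (0.3, 0.2, 0.2)),
        )
        grid = GridSpec((15, 10, 10), (20.0, 20.0, 20.0))
        with pytest.warns(UserWarning, match="discontinuous"):
            vol = vq.voxelize_network(net, grid)
        assert vol.data.sum() == 10

    def test_tube_volume_matches_analytic_within_5pc(self, tube_mask):
        net, vol = tube_mask
        analytic = net.total_volume_mm3()
        assert vol.foreground_volume_mm3() == pytest.approx(analytic, rel=0.05)

    def test_connected_rasterization(self, binary_tree_network):
        from scipy import ndimage

        grid = GridSpec((160, 160, 160), (20.0, 20.0, 20.0))
        vol = vq.voxelize_network(binary_tree_network, grid)
        _, n = ndimage.label(vol.as_bool(), structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_determinism(self, binary_tree_network):
        grid = GridSpec((160, 160, 160), (20.0, 20.0, 20.0))
        a = vq.voxelize_network(binary_tree_network, grid)
        b = vq.voxelize_network(binary_tree_network, grid)
        np.testing.assert_array_equal(a.data, b.data)


class TestGroundTruthDescriptors:
    def test_single_string_volume(self):
        from vasoquant.pipeline_io import make_single_tube_network

        net = make_single_tube_network(radius_mm=0.063, length_mm=8.4)
        ds = network_ground_truth_descriptors(net)
        assert ds["blood_volume_mm3"] == pytest.approx(STRING_VOLUME_MM3, rel=1e-9)
        assert 0.1047 <= ds["blood_volume_mm3"] <= 0.105

    def test_tree_has_no_loops(self, binary_tree_network):
        ds = network_ground_truth_descriptors(binary_tree_network)
        assert (ds["beta0"], ds["beta1"]) == (1, 0)

    def test_two_disjoint_triangles(self):
        pts = {}
        branches = []
        for t, off in enumerate((0.0, 2.0)):
            corners = [
                np.array([0.5 + off, 0.5, 0.5]),
                np.array([1.5 + off, 0.5, 0.5]),
                np.array([1.0 + off, 1.5, 0.5]),
            ]
            for i, c in enumerate(corners):
                pts[3 * t + i] = c
            for i in range(3):
                a, b = 3 * t + i, 3 * t + (i + 1) % 3
                branches.append(
                    Branch(len(branches), a, b, np.vstack([pts[a], pts[b]]), np.array([0.05] * 2))
                )
        net = VesselNetwork(pts, branches, ((0, 0, 0), (5, 3, 2)))
        ds = network_ground_truth_descriptors(net)
        assert (ds["beta0"], ds["beta1"]) == (2, 2)

    def test_empty_network_raises(self):
        net = VesselNetwork({}, [], ((0, 0, 0), (1, 1, 1)))
        with pytest.raises(ValueError):
            network_ground_truth_descriptors(net)
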