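"""Shared fixtures: all test data is generated programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest

import vasoquant as vq
from vasoquant.pipeline_io import (
    make_loop_network,
    make_single_tube_network,
    make_training_labels,
    small_lnet_config,
)
from vasoquant.volume import GridSpec

#: analytic volume of one phantom string: pi * (63 um)^2 * 8.4 mm
STRING_VOLUME_MM3 = float(np.pi * 0.063**2 * 8.4)


@pytest.fixture(scope="session")
def binary_tree_network():
    """Deterministic two-iteration bifurcating L-net: 7 branches, a tree."""
    cfg = vq.GrammarConfig(
        axiom="F",
        productions=[("F", "F[+F][-F]", 1.0)],
        iterations=2,
        branch_angle_deg=(35.0, 0.0),
        segment_length=(0.6, 0.0),
        root_position=(1.6, 1.6, 0.2),
        initial_direction=(0.0, 0.0, 1.0),
        initial_radius=0.06,
        domain_box=((0.0, 0.0, 0.0), (3.2, 3.2, 3.2)),
        rng_seed=0,
    )
    return vq.generate_lnet(cfg)


@pytest.fixture(scope="session")
def tube_mask():
    """Rasterized straight tube, radius 4 voxels (80 um), on a 20 um grid."""
    net = make_single_tube_network(radius_mm=0.08, length_mm=2.0, y_mm=0.8, depth_mm=0.8)
    grid = GridSpec((140, 80, 80), (20.0, 20.0, 20.0))
    return net, vq.voxelize_network(net, grid)


@pytest.fixture(scope="session")
def loop_mask():
    """Rasterized square loop: beta0 = 1, beta1 = 1."""
    net = make_loop_network()
    return net, vq.voxelize_network(net, GridSpec((96, 96, 96), (20.0, 20.0, 20.0)))


@pytest.fixture(scope="session")
def lnet_fixture():
    """One seeded L-net with ground truth, simulated image and RF labels."""
    grid = GridSpec((64, 64, 104), (20.0, 20.0, 20.0))
    cfg = small_lnet_config(7, grid)
    net = vq.generate_lnet(cfg)
    gt = vq.voxelize_network(net, grid)
    sim = vq.simulate_mesoscopy(gt, vq.SimConfig(rng_seed=7))
    labels = make_training_labels(gt)
    return {"network": net, "gt": gt, "sim": sim, "labels": labels}


@pytest.fixture(scope="session")
def string_phantom():
    """Default three-string phantom (126 um strings at 0.5/1/2 mm)."""
    vol, net = vq.make_string_phantom(vq.PhantomConfig())
    return vol, net


@pytest.fixture(scope="session")
def phantom_at_roundtrip(string_phantom):
    """Noiseless simulation -> AT -> skeleton tube graph of the phantom."""
    vol, net = string_phantom
    sim = vq.simulate_mesoscopy(vol, vq.SimConfig(noise_sigma=0.0))
    _, mask = vq.moments_threshold(sim)
    graph = vq.skeleton_to_graph(vq.prune_skeleton(vq.skeletonize_mask(mask)))
    graph = vq.estimate_tube_radii(graph, mask)
    return {"sim": sim, "mask": mask, "graph": graph, "network": net, "gt": vol}
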