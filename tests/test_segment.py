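"""Moment-preserving thresholding, feature bank, random forest, median filter."""

import numpy as np
import pytest

import vasoquant as vq
from vasoquant.pipeline_io import make_single_tube_network, make_training_labels
from vasoquant.segment import (
    FEATURE_FAMILIES,
    extract_voxel_features,
    median_postfilter,
    moments_threshold,
    rf_segment,
    train_rf,
)
from vasoquant.volume import GridSpec, VoxelVolume


def tsai_oracle_bin(data: np.ndarray) -> int:
    """Independent moment-preserving threshold via orthogonal-polynomial
    roots plus exhaustive search over the 256 cut points."""
    hist, edges = np.histogram(data, bins=256, range=(data.min(), data.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    m = [float(np.sum(p * centers**k)) for k in range(4)]
    # z0, z1 are the roots of the degree-2 orthogonal polynomial of the
    # moment functional: det [[m0, m1, m2], [m1, m2, m3], [1, z, z^2]] = 0
    a0 = m[1] * m[3] - m[2] ** 2
    a1 = m[2] * m[1] - m[0] * m[3]
    a2 = m[0] * m[2] - m[1] ** 2
    z = np.sort(np.roots([a2, a1, a0]))
    z0, z1 = float(z[0]), float(z[1])
    p0 = (z1 - m[1]) / (z1 - z0)
    cum = np.cumsum(p)
    return int(np.argmin(np.abs(cum - p0)))


class TestMomentsThreshold:
    def test_two_level_image_recovers_bright_class(self):
        rng = np.random.default_rng(0)
        data = np.where(rng.random((20, 20, 20)) < 0.4, 20.0, 200.0)
        thr, mask = moments_threshold(data)
        assert 20.0 < thr <= 200.0
        np.testing.assert_array_equal(mask > 0, data == 200.0)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            moments_threshold(np.full((5, 5, 5), 3.0))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        n_levels = rng.integers(3, 12)
        levels = rng.choice(256, size=n_levels, replace=False).astype(float)
        counts = rng.integers(1, 400, size=n_levels)
        data = np.repeat(levels, counts)
        rng.shuffle(data)
        thr, _ = moments_threshold(data.reshape(-1, 1, 1))
        _, edges = np.histogram(data, bins=256, range=(data.min(), data.max()))
        oracle = tsai_oracle_bin(data)
        # threshold must be the upper edge of the oracle's cut bin
        assert thr == pytest.approx(edges[min(oracle + 1, 255)])

    def test_moments_preserved_by_bilevel_representation(self):
        rng = np.random.default_rng(5)
        data = np.concatenate(
            [rng.normal(40, 6, 4000), rng.normal(180, 12, 6000)]
        ).clip(0, 255)
        thr, mask = moments_threshold(data.reshape(-1, 1, 1))
        mask = mask.ravel() > 0
        # replace classes by their representative levels: moments must match
        z0, z1 = data[~mask].mean(), data[mask].mean()
        bilevel = np.where(mask, z1, z0)
        for k in (1, 2, 3):
            assert np.mean(bilevel**k) == pytest.approx(np.mean(data**k), rel=0.05)


class TestFeatureBank:
    def test_constant_volume_features(self):
        vol = VoxelVolume(np.full((44, 44, 44), 5.0), (20,) * 3)
        fs = extract_voxel_features(vol)
        for name, chan in zip(fs.names, fs.values):
            if name.startswith("gaussian"):
                np.testing.assert_allclose(chan, 5.0, atol=1e-4)
            elif name.startswith(("gradient", "laplacian", "difference")):
                np.testing.assert_allclose(chan, 0.0, atol=1e-4)

    def test_gradient_peaks_at_step_edge(self):
        data = np.zeros((44, 44, 44))
        data[22:] = 1.0
        fs = extract_voxel_features(VoxelVolume(data, (20,) * 3))
        chan = fs.values[fs.names.index("gradient_magnitude_s1.0")]
        assert 20 <= np.unravel_index(np.argmax(chan), chan.shape)[0] <= 23

    def test_channel_count_matches_shipped_table(self):
        vol = VoxelVolume(np.zeros((44, 44, 44)), (20,) * 3)
        fs = extract_voxel_features(vol)
        expected = sum(n * len(scales) for _, n, scales in FEATURE_FAMILIES)
        assert fs.n_features == expected == 51
        assert len(set(fs.names)) == fs.n_features

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError, match="kernel support"):
            extract_voxel_features(VoxelVolume(np.zeros((10, 10, 10)), (20,) * 3))


def _separable_fixture():
    rng = np.random.default_rng(2)
    gt = np.zeros((44, 44, 44), dtype=np.uint8)
    gt[10:20, 10:20, 10:30] = 1
    image = np.where(gt > 0, 1.0, 0.1)
    labels = np.zeros_like(gt)
    vox_fg = np.argwhere(gt > 0)
    vox_bg = np.argwhere(gt == 0)
    for arr, lab in ((vox_fg, 2), (vox_bg, 1)):
        pick = arr[rng.choice(len(arr), 150, replace=False)]
        labels[pick[:, 0], pick[:, 1], pick[:, 2]] = lab
    vol = VoxelVolume(image, (20,) * 3)
    return vol, gt, VoxelVolume(labels, (20,) * 3)


class TestRandomForest:
    def test_separable_training_recovers_ground_truth(self):
        vol, gt, labels = _separable_fixture()
        feats = extract_voxel_features(vol)
        model = train_rf(feats, labels, n_trees=30, rng_seed=0)
        assert model.training_meta["oob_accuracy"] == pytest.approx(1.0)
        pred = rf_segment(feats, model)
        np.testing.assert_array_equal(pred, gt)

    def test_seed_invariant_predictions_on_separable_data(self):
        vol, gt, labels = _separable_fixture()
        feats = extract_voxel_features(vol)
        a = rf_segment(feats, train_rf(feats, labels, n_trees=30, rng_seed=1))
        b = rf_segment(feats, train_rf(feats, labels, n_trees=30, rng_seed=2))
        # forests differ tree by tree but the decision is stable everywhere
        # except a handful of voxels on the blurred object boundary
        np.testing.assert_array_equal(a[gt > 0], b[gt > 0])
        assert (a != b).mean() < 1e-3

    def test_single_class_labels_raise(self):
        vol, _, labels = _separable_fixture()
        only_bg = labels.with_data(np.where(labels.data == 1, 1, 0))
        feats = extract_voxel_features(vol)
        with pytest.raises(ValueError, match="both"):
            train_rf(feats, only_bg)

    def test_all_background_volume_predicts_empty(self):
        vol, _, labels = _separable_fixture()
        feats = extract_voxel_features(vol)
        model = train_rf(feats, labels, n_trees=30, rng_seed=0)
        flat = VoxelVolume(np.full(vol.data.shape, 0.1), (20,) * 3)
        pred = rf_segment(flat, model)
        assert pred.data.sum() == 0

    def test_feature_mismatch_raises(self):
        vol, _, labels = _separable_fixture()
        feats = extract_voxel_features(vol)
        model = train_rf(feats, labels, n_trees=10)
        model.feature_names = model.feature_names[:-1]
        with pytest.raises(ValueError, match="feature"):
            rf_segment(feats, model)

    def test_rf_beats_at_on_deep_low_snr_tube(self):
        # a faint tube at depth (SNR ~ 3) under a bright shallow tube
        grid = GridSpec((100, 48, 110), (20.0, 20.0, 20.0))
        data = np.zeros(grid.shape)
        for depth in (0.3, 1.9):
            net = make_single_tube_network(length_mm=1.5, y_mm=0.48, depth_mm=depth, x0_mm=0.2)
            data += vq.voxelize_network(net, grid).data
        gt = VoxelVolume((data > 0).astype(np.uint8), grid.spacing_um)
        sim = vq.simulate_mesoscopy(gt, vq.SimConfig(rng_seed=5))
        labels = make_training_labels(gt)
        at = vq.segment_volume(sim, "at")
        rf = vq.segment_volume(sim, "rf", labels=labels, n_trees=50, rng_seed=5)
        deep = slice(80, 110)
        f1_at = vq.voxel_f1(at.data[:, :, deep], gt.data[:, :, deep])[0]
        f1_rf = vq.voxel_f1(rf.data[:, :, deep], gt.data[:, :, deep])[0]
        assert f1_rf > f1_at


class TestMedianFilter:
    def test_isolated_voxel_removed(self):
        m = np.zeros((11, 11, 11), dtype=np.uint8)
        m[5, 5, 5] = 1
        assert median_postfilter(m, 1).sum() == 0

    def test_solid_cube_interior_unchanged(self):
        m = np.zeros((13, 13, 13), dtype=np.uint8)
        m[2:11, 2:11, 2:11] = 1
        out = median_postfilter(m, 1)
        assert np.all(out[3:10, 3:10, 3:10] == 1)

    def test_salt_and_pepper_cleanup_improves_f1(self, tube_mask):
        _, vol = tube_mask
        rng = np.random.default_rng(0)
        clean = vol.as_bool()
        noisy = clean ^ (rng.random(clean.shape) < 0.02)
        before = vq.voxel_f1(noisy, clean)[0]
        after = vq.voxel_f1(median_postfilter(noisy.astype(np.uint8), 1), clean)[0]
        assert after > before

    def test_variant_masks_are_reproducible(self, lnet_fixture):
        sim, labels = lnet_fixture["sim"], lnet_fixture["labels"]
        a = vq.segment_volume(sim, "at")
        b = vq.segment_volume(sim, "at")
        np.testing.assert_array_equal(a.data, b.data)
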