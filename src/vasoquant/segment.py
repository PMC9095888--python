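"""Vessel segmentation: moment-preserving thresholding and random forests.

Two segmenters, mirroring the rule-based/learning-based comparison the
pipeline is built to support:

* **AT** — Tsai's moment-preserving auto-threshold.  The bilevel image that
  preserves the first three intensity moments of the input determines the
  background fraction ``p0``; the threshold is the ``p0``-quantile of a
  256-bin histogram of the whole 3D volume.
* **RF** — a random-forest voxel classifier over a multiscale feature bank
  (intensity, edge and texture descriptors at sigmas 0.3-5.0 voxels),
  trained on sparsely labelled voxels only.

Either mask may be post-filtered with a 3D median filter to remove impulse
noise.  ``segment_volume`` wires the four method variants (at, at+vf, rf,
rf+vf) behind one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import (
    hessian_matrix,
    hessian_matrix_eigvals,
    structure_tensor,
    structure_tensor_eigenvalues,
)
from sklearn.ensemble import RandomForestClassifier

from .enhance import EnhanceConfig, preprocess_volume, sato_vesselness
from .volume import VoxelVolume

__all__ = [
    "FeatureStack",
    "SegmenterModel",
    "moments_threshold",
    "extract_voxel_features",
    "train_rf",
    "rf_segment",
    "median_postfilter",
    "segment_volume",
    "FEATURE_SCALES",
    "FEATURE_FAMILIES",
]

#: Feature-bank sigmas in voxels (ilastik-style ladder, ceiling 5.0).
FEATURE_SCALES: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0)

#: Sigmas used by derivative-based kernels: discrete derivative kernels are
#: ill-conditioned below ~0.7 voxels, so the 0.3 rung is smoothing-only.
DERIVATIVE_SCALES: tuple[float, ...] = FEATURE_SCALES[1:]

#: Kernel families: (name, channels per scale, sigmas).  51 channels total.
FEATURE_FAMILIES: tuple[tuple[str, int, tuple[float, ...]], ...] = (
    ("gaussian", 1, FEATURE_SCALES),
    ("gradient_magnitude", 1, DERIVATIVE_SCALES),
    ("laplacian_of_gaussian", 1, DERIVATIVE_SCALES),
    ("difference_of_gaussians", 1, DERIVATIVE_SCALES),
    ("hessian_eigenvalue", 3, DERIVATIVE_SCALES),
    ("structure_tensor_eigenvalue", 3, DERIVATIVE_SCALES),
)


# ---------------------------------------------------------------------------
# Moment-preserving (Tsai) auto-threshold
# ---------------------------------------------------------------------------


def moments_threshold(volume: VoxelVolume | np.ndarray) -> tuple[float, VoxelVolume | np.ndarray]:
    """Tsai's moment-preserving bilevel threshold on a 256-bin histogram.

    Solves for the two-point distribution ``(z0, p0), (z1, p1)`` whose first
    three moments equal those of the image, then thresholds at the gray
    level where the cumulative histogram fraction reaches ``p0``.  The mask
    is ``volume >= threshold``.  Deterministic; raises on constant images.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("constant image: no moment-preserving threshold exists")
    hist, edges = np.histogram(data, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    m1 = float(np.sum(p * centers))
    m2 = float(np.sum(p * centers**2))
    m3 = float(np.sum(p * centers**3))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: zero variance")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 <= z0:
        raise ValueError("degenerate histogram: coincident representative levels")
    p0 = float(np.clip((z1 - m1) / (z1 - z0), 0.0, 1.0))
    cum = np.cumsum(p)
    # cut bin whose below-threshold fraction is nearest the target p0
    t_bin = int(np.argmin(np.abs(cum - p0)))
    threshold = float(edges[min(t_bin + 1, 255)])
    mask = (data >= threshold).astype(np.uint8)
    if isinstance(volume, VoxelVolume):
        return threshold, volume.with_data(mask)
    return threshold, mask


# ---------------------------------------------------------------------------
# Random-forest voxel classification
# ---------------------------------------------------------------------------


@dataclass
class FeatureStack:
    """Per-voxel feature bank: ``values`` has shape (n_features, nx, ny, nz)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.names):
            raise ValueError("one name per feature channel required")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def matrix(self, selection: np.ndarray | None = None) -> np.ndarray:
        """Feature matrix (n_voxels, n_features); optionally at a boolean mask."""
        if selection is None:
            return self.values.reshape(self.n_features, -1).T
        return self.values[:, selection].T


def extract_voxel_features(volume: VoxelVolume | np.ndarray) -> FeatureStack:
    """Compute the multiscale feature bank used by the voxel classifier.

    Six kernel families (Gaussian smoothing, gradient magnitude, Laplacian of
    Gaussian, difference of Gaussians, Hessian eigenvalues, structure-tensor
    eigenvalues) over the sigma ladder 0.3-5.0 voxels; eigenvalue families
    contribute three channels each and derivative kernels skip the 0.3 rung,
    for 51 channels total (see ``FEATURE_FAMILIES``).
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    data = data.astype(np.float32)
    support = int(2 * np.ceil(2 * max(FEATURE_SCALES)) + 1)
    if min(data.shape) < support:
        raise ValueError(
            f"volume shape {data.shape} is smaller than the largest kernel support ({support})"
        )
    channels: list[np.ndarray] = []
    names: list[str] = []

    def add(name: str, arr: np.ndarray) -> None:
        channels.append(arr.astype(np.float32))
        names.append(name)

    for s in FEATURE_SCALES:
        add(f"gaussian_s{s}", ndimage.gaussian_filter(data, sigma=s))
    # derivative kernels act on mean-centred data: small-sigma discrete
    # kernels have a slight DC leak that would otherwise bias the channels
    data = data - data.mean()
    for s in DERIVATIVE_SCALES:
        smooth = ndimage.gaussian_filter(data, sigma=s)
        add(f"gradient_magnitude_s{s}", ndimage.gaussian_gradient_magnitude(data, sigma=s))
        add(f"laplacian_of_gaussian_s{s}", ndimage.gaussian_laplace(data, sigma=s))
        add(f"difference_of_gaussians_s{s}", smooth - ndimage.gaussian_filter(data, sigma=1.6 * s))
        helems = hessian_matrix(data, sigma=s, use_gaussian_derivatives=True)
        heig = hessian_matrix_eigvals(helems)
        for k in range(3):
            add(f"hessian_eigenvalue{k}_s{s}", heig[k])
        st = structure_tensor(data, sigma=s, mode="nearest")
        steig = structure_tensor_eigenvalues(st)
        for k in range(3):
            add(f"structure_tensor_eigenvalue{k}_s{s}", steig[k])
    stack = FeatureStack(np.stack(channels), names)
    if not np.isfinite(stack.values).all():
        raise ValueError("non-finite feature values")
    return stack


@dataclass
class SegmenterModel:
    """A trained voxel classifier plus the feature configuration it expects."""

    forest: RandomForestClassifier
    feature_names: list[str]
    training_meta: dict = field(default_factory=dict)

    @property
    def feature_importances(self) -> np.ndarray:
        return self.forest.feature_importances_


def train_rf(
    features: FeatureStack,
    labels: VoxelVolume | np.ndarray,
    n_trees: int = 100,
    rng_seed: int = 0,
    max_samples_per_class: int | None = 20_000,
) -> SegmenterModel:
    """Train a random forest on sparsely labelled voxels.

    ``labels``: 0 = unlabelled, 1 = background, 2 = vessel.  Only labelled
    voxels enter training; when a class has more than
    ``max_samples_per_class`` labelled voxels a seeded random subsample is
    used (forest accuracy saturates well below that while training time does
    not).  Identical seed and data give an identical model.
    """
    lab = labels.data if isinstance(labels, VoxelVolume) else np.asarray(labels)
    if lab.shape != features.values.shape[1:]:
        raise ValueError("label volume shape must match the feature volume shape")
    sel = lab > 0
    y = (lab[sel] == 2).astype(np.int8)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels must contain both background and vessel voxels")
    x = features.matrix(sel)
    if max_samples_per_class is not None:
        rng = np.random.default_rng(rng_seed)
        keep = np.zeros(len(y), dtype=bool)
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if len(idx) > max_samples_per_class:
                idx = rng.choice(idx, size=max_samples_per_class, replace=False)
            keep[idx] = True
        x, y = x[keep], y[keep]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(rng_seed),
        oob_score=True,
        n_jobs=-1,
    )
    forest.fit(x, y)
    meta = {
        "rng_seed": int(rng_seed),
        "n_vessel_labels": int(y.sum()),
        "n_background_labels": int((y == 0).sum()),
        "oob_accuracy": float(forest.oob_score_),
    }
    return SegmenterModel(forest, list(features.names), meta)


def rf_segment(
    volume: VoxelVolume | FeatureStack,
    model: SegmenterModel,
    chunk_voxels: int = 2_000_000,
) -> VoxelVolume | np.ndarray:
    """Classify every voxel with a trained model (vessel if P >= 0.5).

    Accepts a grayscale volume (features computed on the fly) or a
    precomputed :class:`FeatureStack`.
    """
    if isinstance(volume, FeatureStack):
        features = volume
        wrap = None
    else:
        features = extract_voxel_features(volume)
        wrap = volume
    if features.names != model.feature_names:
        raise ValueError("feature configuration does not match the trained model")
    shape = features.values.shape[1:]
    x = features.matrix()
    vessel_col = int(np.argmax(model.forest.classes_ == 1))
    out = np.empty(x.shape[0], dtype=np.uint8)
    for start in range(0, x.shape[0], chunk_voxels):
        proba = model.forest.predict_proba(x[start : start + chunk_voxels])[:, vessel_col]
        out[start : start + chunk_voxels] = proba >= 0.5
    mask = out.reshape(shape)
    if wrap is not None:
        return wrap.with_data(mask)
    return mask


def median_postfilter(mask: VoxelVolume | np.ndarray, radius_voxels: int = 1):
    """3D median filter over a cubic (2r+1)^3 neighbourhood of a binary mask."""
    data = mask.data if isinstance(mask, VoxelVolume) else np.asarray(mask)
    size = 2 * int(radius_voxels) + 1
    out = ndimage.median_filter((data > 0).astype(np.uint8), size=size)
    if isinstance(mask, VoxelVolume):
        return mask.with_data(out)
    return out


# ---------------------------------------------------------------------------
# Method variants
# ---------------------------------------------------------------------------


def segment_volume(
    image: VoxelVolume,
    method: str = "at",
    labels: VoxelVolume | np.ndarray | None = None,
    model: SegmenterModel | None = None,
    enhance_config: EnhanceConfig | None = None,
    preprocess: bool = False,
    median_radius: int = 1,
    n_trees: int = 100,
    rng_seed: int = 0,
) -> VoxelVolume:
    """Run one of the four segmentation variants end to end.

    ``method`` is one of ``at``, ``at+vf``, ``rf``, ``rf+vf``; the ``+vf``
    variants insert Sato vesselness filtering before segmentation.  RF
    methods require either sparse ``labels`` (a model is trained on this
    image) or a pre-trained ``model``.  The mask is median post-filtered.
    """
    method = method.lower()
    if method not in {"at", "at+vf", "rf", "rf+vf"}:
        raise ValueError(f"unknown method {method!r}")
    work = preprocess_volume(image, enhance_config) if preprocess else image
    if method.endswith("+vf"):
        work = sato_vesselness(work, enhance_config)
    if method.startswith("at"):
        _, mask = moments_threshold(work)
    else:
        if model is None:
            if labels is None:
                raise ValueError("rf segmentation needs labels or a trained model")
            feats = extract_voxel_features(work)
            model = train_rf(feats, labels, n_trees=n_trees, rng_seed=rng_seed)
            mask = rf_segment(feats, model)
            mask = work.with_data(mask.reshape(work.data.shape))
        else:
            mask = rf_segment(work, model)
    if median_radius > 0:
        mask = median_postfilter(mask, median_radius)
    return mask
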