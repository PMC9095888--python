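# Methods

`vasoquant` quantifies 3D vascular networks in mesoscopic photoacoustic
images. Because real acquisitions have no voxel-level ground truth, the
package pairs the analysis pipeline with a synthetic-data path whose
geometry and topology are known exactly. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not show about real data.

## Synthetic vascular networks (L-nets)

Ground-truth networks are generated by a stochastic Lindenmayer system. An
axiom string is rewritten for a configurable number of iterations; each
symbol occurrence picks a production at random according to the configured
probabilities (which must sum to one per predecessor). The resulting string
drives a 3D turtle: `F` draws a tubular segment whose length is drawn from a
normal distribution, `+ - & ^ / \` rotate the turtle frame by angles drawn
from a normal distribution, and `[ ]` push/pop the state to create side
branches. Coincident segments produced by the rewriting (which occur in
deterministic grammars, where a child's leading `F` retraces its parent's
continuation) collapse onto shared nodes and branches, and maximal chains
through degree-2 nodes are fused, so a branch is a vessel segment between
junctions/endpoints.

Radius inheritance follows Murray's law with exponent `g` (default 3):
at each `[` the child radius is `r * 2^(-1/g)`, the symmetric-bifurcation
solution of `r_parent^g = sum r_child^g`; the continuing trunk keeps its
radius. A floor (`min_radius`, default 15 µm) keeps radii resolvable.

Defaults (`GrammarConfig`): six iterations of a grammar dominated by a
bifurcating production, branch angles 35° ± 8°, segment lengths
0.40 ± 0.08 mm, initial radius 0.12 mm, rooted at the top surface of a
10.24 × 10.24 × 2.80 mm³ domain and growing into depth. The published
grammars behind comparable studies are not available; these values were
chosen once so that networks span the full imaging depth and have total
blood volumes of order 0.1–1 mm³ per fixture-scale domain (the range those
studies report in aggregate), and the grammar is fully config-driven so any
other rule set can be expressed. Segments that would leave the domain are
clipped at the boundary (and counted); the turtle stops drawing beyond a
clipped segment so networks stay connected.

**Rasterization.** Centerlines are drawn with an integer 3D Bresenham line
(26-connected chains); every voxel whose centre lies within the local radius
of the centerline — measured in physical units, so anisotropic grids are
handled — is set. Coordinates are millimetres, arrays are indexed
`[x, y, z]` with depth last, and voxel `i` is centred at `origin + i *
spacing` (a structure at 0.5 mm depth on a 20 µm grid sits on slice 25).
For tubes of radius ≥ 3 voxels the voxelized volume agrees with the
analytic `sum(pi r^2 ds)` within 5%; thinner tubes are increasingly
quantised (the centerline chain itself is always drawn, with a warning when
the radius is below half a voxel).

## Surrogate forward model

The imaging simulation is a separable surrogate, not a wave-physics
simulation: amplitude decays as `exp(-mu_eff z)` (fluence), the result is
blurred by an anisotropic Gaussian PSF (FWHM 40 µm lateral / 10 µm axial,
the resolution of the mesoscopy system being emulated), optionally passed
through an axial difference-of-Gaussians band-pass and summed with an
attenuated, depth-shifted echo copy, and finally corrupted by i.i.d.
Gaussian noise (`noise_sigma`, as a fraction of the surface signal).
Defaults: `mu_eff = 1.0 mm^-1`, `noise_sigma = 0.05`, echo and band-pass
off. With these defaults the depth-binned SNR of simulated networks decays
monotonically from ~15 near the surface to below 2 at 2.4 mm — the regime
in which rule-based and learning-based segmentation genuinely diverge.

What the surrogate reproduces: depth-dependent SNR decay, anisotropic blur,
echo artefacts, noise. What it does not: speckle, reconstruction artefacts,
reflection lines, spatially varying sensitivity, frequency-dependent
acoustic attenuation. Conclusions drawn from the synthetic benchmark
therefore concern the *relative* behaviour of the methods under depth-
dependent signal loss, not absolute in vivo performance.

**String phantom.** The synthetic twin of a three-string agar phantom:
strings of diameter 126 µm and length 8.4 mm at depths 0.5/1/2 mm, each an
analytic cylinder of volume 0.1047 mm³. `partial_illumination_mask` keeps
only the surface-facing fraction of each tube's cross-section (per depth
column, each contiguous run keeps its shallowest `ceil(f * run)` voxels),
emulating top-surface illumination where the deep half of a string emits no
detectable signal.

## Pre-processing and vesselness

Pre-processing applies, in order: a spatial high-pass (input minus a
Gaussian low-pass, sigma 10 voxels laterally), a local mean/variance
(Wiener) filter with a 3 × 3 window, and a slice-wise background
subtraction (per-slice 25th percentile removed, negatives clipped). All
three act within depth slices: axial sampling of reconstructed stacks is
much finer than lateral sampling, the echo background being removed is a
lateral structure, and slice-wise operation makes the pipeline exactly
invariant to per-slice additive offsets.

Vesselness is Sato's bright-line measure on the eigenvalues of the
Gaussian-scale Hessian. Derivatives are taken in physical units (per-axis
sigma = scale / spacing) and gamma-normalised (multiplied by sigma²).
With eigenvalues ordered by magnitude `|l1| <= |l2| <= |l3|`, voxels with
`l2, l3 < 0` (bright tube cross-section) score `|l2|`, modulated by
`(1 + l1/|l2|)` when `l1 <= 0` and `(1 - alpha l1/|l2|)` when `l1 > 0`
(`alpha = 0.25`; both Sato exponents fixed at 1). The final map is the
voxelwise maximum over the scale ladder 20/40/60/80/100 µm.

Scales are *vessel diameters*: the kernel sigma is `scale / (2 sqrt 2)`,
because the gamma-normalised response of a solid cylinder of radius R peaks
at `sigma = R / sqrt 2`. With this mapping a 60 µm tube responds maximally
at the 60 µm scale (verified numerically for 40/60/80 µm tubes), so the
ladder reads directly in vessel sizes.

## Segmentation

**Auto-threshold (AT).** Tsai's moment-preserving threshold on a 256-bin
histogram of the whole 3D volume: the two-point distribution matching the
image's first three moments is solved in closed form, and the threshold is
the gray level whose below-threshold fraction is nearest the background
weight `p0`. The mask is `volume >= threshold`. A constant image has no
such threshold and raises.

**Random forest (RF).** A voxel classifier over a 51-channel feature bank:
Gaussian smoothing, gradient magnitude, Laplacian of Gaussian, difference
of Gaussians, Hessian eigenvalues (3) and structure-tensor eigenvalues (3)
at sigmas 0.3–5.0 voxels (derivative kernels skip the 0.3 rung, where
discrete derivative kernels are ill-conditioned; they also act on
mean-centred data to cancel the residual DC leak of small kernels).
Training uses labelled voxels only (0 unlabelled / 1 background / 2
vessel); the synthetic labelling scheme marks all vessel voxels, a
10-voxel background shell around them, and three full planes parallel to
the depth axis. At most 20 000 voxels per class (seeded subsample) enter
the forest — accuracy saturates far below that, training time does not.
Forest: 100 trees, unlimited depth, sqrt-features per split, fixed seed;
ties at probability 0.5 go to vessel (favouring recall for thin
structures). Both paths can take vesselness-filtered input (`at+vf`,
`rf+vf`), and masks are post-filtered with a 3D median filter (radius 1
voxel) to remove impulse noise.

## Skeletonisation and tube graphs

Masks are thinned with a homotopic 3D thinning algorithm (Lee's method, as
implemented in scikit-image), which preserves the digital object's
connected components and loops. Per-voxel radii come from the Euclidean
distance transform of the mask with the physical voxel spacing as sampling.

The skeleton's 26-adjacency graph is cleaned of redundant diagonal edges
(a diagonal adjacency that only duplicates a two-step path of face/edge
adjacencies is dropped, processed in decreasing rank so connectivity is
never broken) — without this, triangle closures at junctions inflate
degrees and read as spurious one-voxel loops. Voxels with other than two
neighbours become nodes, touching node voxels merge into one junction
node, maximal degree-2 chains become branches with ordered polylines and
radii, and components that are pure cycles keep an anchor node carrying a
self-loop, so graph Betti numbers (`beta0` = components, `beta1 = E - V +
beta0`) equal those of the digital skeleton.

**Pruning** iteratively removes terminal branches shorter than
`max(40 µm, 2 × junction radius)` — thinning artefacts at tube ends — and
never touches loops or isolated paths, preserving homotopy.

**Tube-radius refit.** For volume estimation, each branch is refit with a
single axisymmetric-tube radius measured from mask cross-sections sampled
along the branch (plane orthogonal to the local tangent, sampled at half
the voxel spacing). If the cross-section area is consistent with the disc
of its inscribed radius, the radius is `max(EDT radius, inscribed
radius)`; if the area exceeds the inscribed disc by more than 50%, the
section is a partially detected tube (e.g. top-surface illumination) whose
width still spans the full vessel, and the radius is half the extent along
the section's principal axis (robust to the diagonal inflation a pairwise
Feret diameter picks up on crescents). On a half-illuminated 126 µm string
the voxel-count volume underestimates truth by ~40% while the fitted tube
volume is within ~7%; this is the mechanism that makes skeleton-derived
volumes more faithful than segmented voxel counts for partially detected
vessels.

## Descriptors

Per branch: arc length (mm), diameter (2 × mean per-point radius, mm),
tortuosity as the sum-of-angles measure (SOAM) — at each interior point the
in-plane angle between consecutive step vectors combined with the torsional
angle between consecutive osculating-plane normals as `sqrt(IP² + TP²)`,
summed and divided by path length, reported in rad/mm (an in-plane-only
switch exists) — and curvature as the chord-to-length ratio (CLR),
endpoint distance over arc length, in (0, 1], 1 for straight vessels (the
inverse convention is deliberately not used). Per network: `beta0`,
`beta1` (computed on the branch graph — the skeleton graph carries exactly
the loop information meant by "1D holes of the network"), edge and node
counts, and the tube-model blood volume `sum(pi r̄² ds)`; optional
normalisations by an ROI volume. Distribution-level summaries use medians.

## Evaluation

* **SNR by depth**: mean image intensity over ground-truth foreground
  voxels in a depth bin divided by the standard deviation over background
  voxels in the bin; background excludes a 5-voxel dilation of the ground
  truth to avoid PSF bleed. Zero-noise bins report `inf`; empty bins are
  omitted.
* **Voxel F1** `2TP / (2TP + FP + FN)`, with precision/recall; two empty
  masks score 1 by convention, empty truth against non-empty prediction 0.
* **Regression metrics**: MSE, and R² of a univariate linear model
  predicting truth from method estimates, with bootstrap optimism
  correction (default R = 500, seeded): fit on each resample, score on the
  resample and on the original data, subtract the mean score difference.
* **Bland–Altman**: differences are `reference - method` (positive bias =
  underestimation), bias ± 1.96 sd (n−1 denominator).

`benchmark_methods` runs the four variants (at, at+vf, rf, rf+vf) end to
end over ground-truth fixtures and emits a tidy per-(fixture, method)
table; stage failures mark the row and the run continues.

## Problem sizes and reproducibility

Every stochastic step is seeded (`numpy.random.default_rng`), and identical
configuration + seed reproduce networks, simulations and forests exactly.
The test suite and the acceptance script use desk-scale problems chosen to
exercise the full depth range at 20 µm resolution: the full-size phantom
grid is 448 × 80 × 140 voxels, L-net benchmark fixtures are 64 × 64 × 104
(1.28 × 1.28 × 2.08 mm³), and the four-method comparisons use 2 mm strings
on a 128 × 48 × 128 grid. CLI runs record configs, seeds and output
checksums in a JSON manifest.

## Known limitations

* A single global threshold cannot track the `exp(-mu_eff z)` amplitude
  decay: with the default attenuation, strings deeper than ~1 mm are
  thresholded far from their half-maximum (or lost entirely), so their
  absolute volumes are underestimated — the same depth dependence the
  rule-based method shows on real phantoms. Depth-adaptive or learning-
  based segmentation is required for quantitative accuracy at depth.
* The skeletonisation path is thinning + pruning; no learning-based
  centerline extraction, and no reconnection of subnetworks severed by
  segmentation gaps.
* The grammar defaults emulate generic branching vasculature, not any
  organ-specific architecture, and the surrogate forward model omits wave
  physics (see above); quantitative claims transfer to real data only at
  the level of method orderings and qualitative depth trends.
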