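# vasoquant

Quantification of 3D vascular networks in mesoscopic photoacoustic imaging.

Raster-scan optoacoustic mesoscopy (RSOM) resolves blood vessels of
~20–100 µm diameter down to ~3 mm depth, but turning those image volumes
into biology — blood volume, vessel diameters and lengths, tortuosity,
network topology — requires a chain of processing steps (enhancement,
segmentation, skeletonisation, descriptor extraction) whose choices change
the answers. `vasoquant` implements that full chain **together with a
synthetic ground-truth path** so every step can be validated end to end:

* **vascgen** — stochastic L-system vascular networks ("L-nets") with
  fully known per-branch geometry and topology, rasterized to binary
  volumes (3D Bresenham centerlines + physical-radius filling);
* **mesosim** — a surrogate photoacoustic forward model
  (`exp(-mu_eff z)` fluence decay × anisotropic PSF × optional band-pass /
  echo + Gaussian noise) and a synthetic three-string phantom
  (126 µm strings at 0.5/1/2 mm depth);
* **enhance** — high-pass / Wiener / slice-wise background correction, and
  multiscale Sato vesselness (α = 0.25, scales 20–100 µm);
* **segment** — moment-preserving auto-thresholding (AT) and a trainable
  random-forest voxel classifier (RF), each with optional vesselness input
  and 3D median post-filtering;
* **skeleton** — homotopic thinning, pruning, branch-graph extraction and
  axisymmetric tube-radius fitting;
* **descriptors** — diameters, lengths, sum-of-angles tortuosity (SOAM),
  chord-to-length ratio (CLR), Betti numbers β₀/β₁, tube-model blood
  volume;
* **evaluate** — SNR by depth, voxel F1, MSE/R² with bootstrap optimism
  correction, Bland–Altman agreement, and a four-method benchmark harness.

The scientific core: a segmented mask counts only *detected* voxels, so
partially illuminated vessels are underestimated; representing vessels as
axisymmetric tubes fitted to skeleton cross-sections recovers the full
volume, because the detected section still spans the vessel's width. The
package quantifies both estimates against analytic ground truth. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import numpy as np
import vasoquant as vq

# build the synthetic three-string phantom (126 um strings at 0.5/1/2 mm)
phantom, network = vq.make_string_phantom(vq.PhantomConfig())
print(f"ground truth: {network.n_branches} strings, "
      f"{network.total_volume_mm3() / 3:.4f} mm^3 each")

# noiseless surrogate image, auto-threshold, skeletonise, fit tubes
image = vq.simulate_mesoscopy(phantom, vq.SimConfig(noise_sigma=0.0))
threshold, mask = vq.moments_threshold(image)
graph = vq.skeleton_to_graph(vq.prune_skeleton(vq.skeletonize_mask(mask)))
graph = vq.estimate_tube_radii(graph, mask)

for b in sorted(graph.branches, key=lambda b: b.points[:, 2].mean()):
    volume = float(np.pi * np.mean(b.radii) ** 2 * b.length_mm)
    print(f"string at {b.points[:, 2].mean():.2f} mm depth: "
          f"radius {1e3 * b.radii[0]:.1f} um, tube volume {volume:.4f} mm^3")
```

prints

```
ground truth: 3 strings, 0.1047 mm^3 each
string at 0.50 mm depth: radius 63.2 um, tube volume 0.1056 mm^3
string at 1.00 mm depth: radius 60.0 um, tube volume 0.0941 mm^3
```

The shallow string's tube volume (0.1056 mm³) matches the analytic
0.1047 mm³ within 1%. The 1 mm string is already underestimated by ~10%
and the 2 mm string is lost entirely: with fluence decaying as
`exp(-z/mm)`, a single global threshold cannot track the signal at depth —
exactly the failure mode of rule-based segmentation that the benchmark
harness (`vasoquant.benchmark_methods`) quantifies, and the reason the
trained random-forest variants dominate at depth (their deepest-third F1
is ≥ the auto-threshold's on every seeded fixture).

A command-line interface mirrors the library
(`vasoquant generate | phantom | simulate | enhance | segment |
skeletonize | describe | evaluate | benchmark | pipeline | fixtures`);
every run writes a JSON manifest with configs, seeds and output checksums.

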