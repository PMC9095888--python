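"""Shared I/O, run manifests and fixture generation.

Volumes travel as multi-page TIFF (with a JSON sidecar carrying the voxel
spacing) or NIfTI-1 (spacing in the header); networks and graphs export to
CSV edge/point lists, GraphML and SWC.  Every CLI stage writes a
:class:`RunManifest` recording configs, seeds and output checksums so a run
can be reproduced bit for bit.

Axis conventions (see :mod:`vasoquant.volume`): arrays are ``[x, y, z]``
with depth last; TIFF pages are z-slices (the file stores ``[z, y, x]``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .vascgen import Branch, GrammarConfig, VesselNetwork, generate_lnet, voxelize_network
from .volume import GridSpec, VoxelVolume

__all__ = [
    "load_volume",
    "save_volume",
    "RunManifest",
    "make_training_labels",
    "make_fixture_suite",
    "make_single_tube_network",
    "make_loop_network",
    "write_network_csv",
    "write_network_graphml",
    "write_graph_swc",
]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def load_volume(path, expected_spacing_um=None) -> VoxelVolume:
    """Read a TIFF or NIfTI volume with spacing metadata.

    NIfTI spacing comes from the header; TIFF needs a ``<name>.json``
    sidecar (written by :func:`save_volume`) or an ``expected_spacing_um``.
    A mismatch between header/sidecar spacing and ``expected_spacing_um``
    raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path} does not exist")
    suffix = path.name.lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) * 1000.0 for z in zooms)  # mm -> um
        origin = (0.0, 0.0, 0.0)
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(str(path))
        if pages.ndim != 3:
            raise ValueError(f"{path} is not a 3D stack")
        data = np.transpose(pages, (2, 1, 0))  # (z, y, x) pages -> (x, y, z)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta["spacing_um"])
            origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
        elif expected_spacing_um is not None:
            spacing = tuple(float(s) for s in expected_spacing_um)
            origin = (0.0, 0.0, 0.0)
        else:
            raise ValueError(
                f"no spacing metadata for {path}: provide a {sidecar.name} sidecar "
                "or pass expected_spacing_um"
            )
    else:
        raise ValueError(f"unsupported volume format: {path} (use .tif/.tiff/.nii/.nii.gz)")
    if expected_spacing_um is not None and not np.allclose(
        spacing, expected_spacing_um, rtol=1e-4
    ):
        raise ValueError(
            f"spacing mismatch for {path}: file says {spacing} um, expected {expected_spacing_um}"
        )
    return VoxelVolume(data, spacing, origin)


def save_volume(volume: VoxelVolume, path, scale_binary: bool = False) -> Path:
    """Write a volume as TIFF (+ JSON spacing sidecar) or NIfTI.

    ``scale_binary=True`` stores a 0/1 mask as 8-bit 0/255 (viewer-friendly
    ground-truth convention).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if scale_binary:
        data = (data > 0).astype(np.uint8) * 255
    suffix = path.name.lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms(tuple(volume.spacing_mm))
        nib.save(img, str(path))
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.transpose(data, (2, 1, 0)))
        _sidecar_path(path).write_text(
            json.dumps({"spacing_um": list(volume.spacing_um), "origin_mm": list(volume.origin_mm)})
        )
    else:
        raise ValueError(f"unsupported volume format: {path}")
    return path


# ---------------------------------------------------------------------------
# Network / graph exports
# ---------------------------------------------------------------------------


def write_network_csv(network_or_graph, out_prefix) -> tuple[Path, Path]:
    """Write an edge-list CSV and a points CSV for a network or graph."""
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges, points = [], []
    for b in network_or_graph.branches:
        edges.append(
            {
                "branch_id": b.id,
                "start_node": b.start_node,
                "end_node": b.end_node,
                "length_mm": b.length_mm,
                "mean_radius_mm": b.mean_radius_mm,
            }
        )
        for p, r in zip(b.points, b.radii):
            points.append({"branch_id": b.id, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2], "r_mm": r})
    edge_path = out_prefix.with_name(out_prefix.name + "_edges.csv")
    point_path = out_prefix.with_name(out_prefix.name + "_points.csv")
    pd.DataFrame(edges).to_csv(edge_path, index=False)
    pd.DataFrame(points).to_csv(point_path, index=False)
    return edge_path, point_path


def write_network_graphml(network_or_graph, path) -> Path:
    import networkx as nx

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = network_or_graph.as_multigraph()
    out = nx.MultiGraph()
    for n, data in g.nodes(data=True):
        pos = data.get("position")
        attrs = {}
        if pos is not None:
            attrs = {"x_mm": float(pos[0]), "y_mm": float(pos[1]), "z_mm": float(pos[2])}
        out.add_node(n, **attrs)
    for u, v, k, data in g.edges(keys=True, data=True):
        b = data.get("branch")
        out.add_edge(
            u,
            v,
            key=k,
            length_mm=float(b.length_mm) if b is not None else 0.0,
            mean_radius_mm=float(b.mean_radius_mm) if b is not None else 0.0,
        )
    nx.write_graphml(out, str(path))
    return path


def write_graph_swc(network_or_graph, path) -> Path:
    """SWC export (structure id 0, soma-free) for viewer compatibility.

    SWC encodes rooted trees; each branch is written as a chain of samples
    whose first sample has parent -1 when it starts a component, so cyclic
    graphs are representable at the cost of duplicated junction samples.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# SWC export (structure id 0), coordinates in mm"]
    sid = 0
    for b in network_or_graph.branches:
        parent = -1
        for p, r in zip(b.points, b.radii):
            sid += 1
            lines.append(f"{sid} 0 {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r:.6f} {parent}")
            parent = sid
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: stages with configs, seeds and checksums."""

    stages: list[dict] = field(default_factory=list)
    version: str = __version__
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_stage(self, name: str, config=None, seed=None, inputs=(), outputs=()) -> None:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            config = _config_to_json(config)
        self.stages.append(
            {
                "name": name,
                "config": config,
                "seed": seed,
                "inputs": [str(p) for p in inputs],
                "outputs": [
                    {"path": str(p), "sha256": _sha256(Path(p))} for p in outputs
                ],
            }
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(stages=raw["stages"], version=raw["version"], created=raw["created"])


def _config_to_json(config) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            v = _config_to_json(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_from_json(cls, payload: dict):
    """Build a config dataclass from a JSON dict (nested GridSpec supported)."""
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    for key, value in payload.items():
        if key not in names:
            raise ValueError(f"unknown {cls.__name__} field: {key!r}")
        if key == "grid" and isinstance(value, dict):
            value = GridSpec(
                tuple(value["shape"]),
                tuple(value.get("spacing_um", (20.0, 20.0, 20.0))),
                tuple(value.get("origin_mm", (0.0, 0.0, 0.0))),
            )
        elif isinstance(value, list) and value and isinstance(value[0], list):
            value = [tuple(v) for v in value] if key == "productions" else tuple(
                tuple(v) for v in value
            )
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_training_labels(
    gt_mask: VoxelVolume, shell_radius_vox: int = 10, n_planes: int = 3
) -> VoxelVolume:
    """Sparse training labels mimicking the synthetic labelling scheme.

    All vessel voxels are labelled vessel (2); background labels (1) cover a
    ``shell_radius_vox`` shell around the vessels plus ``n_planes`` full
    planes parallel to the depth axis (edges and middle), leaving the rest
    unlabelled (0).
    """
    from scipy import ndimage

    fg = gt_mask.as_bool()
    labels = np.zeros(fg.shape, dtype=np.uint8)
    shell = ndimage.binary_dilation(fg, iterations=shell_radius_vox) & ~fg
    labels[shell] = 1
    nx = fg.shape[0]
    plane_idx = np.unique(np.linspace(0, nx - 1, max(n_planes, 1)).astype(int))
    for i in plane_idx:
        plane = labels[i]
        plane[~fg[i]] = 1
        labels[i] = plane
    labels[fg] = 2
    return gt_mask.with_data(labels)


def make_single_tube_network(
    radius_mm: float = 0.063,
    length_mm: float = 8.4,
    depth_mm: float = 0.5,
    y_mm: float = 0.8,
    x0_mm: float = 0.2,
) -> VesselNetwork:
    """A single straight tube along x — the minimal analytic fixture."""
    a = np.array([x0_mm, y_mm, depth_mm])
    b = np.array([x0_mm + length_mm, y_mm, depth_mm])
    box = ((0.0, 0.0, 0.0), (x0_mm + length_mm + 0.2, 2 * y_mm, depth_mm + 1.0))
    return VesselNetwork(
        {0: a, 1: b}, [Branch(0, 0, 1, np.vstack([a, b]), np.array([radius_mm] * 2))], box
    )


def make_loop_network(
    side_mm: float = 1.0, radius_mm: float = 0.06, depth_mm: float = 0.6
) -> VesselNetwork:
    """A square loop of four branches: beta0 = 1, beta1 = 1."""
    c = 0.4
    pts = [
        np.array([c, c, depth_mm]),
        np.array([c + side_mm, c, depth_mm]),
        np.array([c + side_mm, c + side_mm, depth_mm]),
        np.array([c, c + side_mm, depth_mm]),
    ]
    nodes = dict(enumerate(pts))
    branches = [
        Branch(i, i, (i + 1) % 4, np.vstack([pts[i], pts[(i + 1) % 4]]), np.array([radius_mm] * 2))
        for i in range(4)
    ]
    box = ((0.0, 0.0, 0.0), (2 * c + side_mm, 2 * c + side_mm, depth_mm + 1.0))
    return VesselNetwork(nodes, branches, box)


def small_lnet_config(rng_seed: int, grid: GridSpec | None = None) -> GrammarConfig:
    """Desk-scale L-net configuration used by the fixture suite.

    Networks are rooted at the top surface, grow into depth and fill a
    1.92 x 1.92 x 2.56 mm domain (96 x 96 x 128 voxels at 20 µm), producing
    ground-truth volumes of order 0.1-1 mm^3.
    """
    grid = grid or GridSpec((96, 96, 128), (20.0, 20.0, 20.0))
    extent = grid.extent_mm
    return GrammarConfig(
        iterations=5,
        root_position=(extent[0] / 2, extent[1] / 2, 0.0),
        initial_radius=0.10,
        branch_angle_deg=(35.0, 10.0),
        segment_length=(0.42, 0.08),
        min_radius=0.02,
        domain_box=((0.0, 0.0, 0.0), tuple(extent - 0.02)),
        rng_seed=rng_seed,
    )


def make_fixture_suite(out_dir, rng_seed: int = 0, n_lnets: int = 5) -> RunManifest:
    """Generate the standard fixture set: L-nets, phantom, degenerate cases.

    Every fixture is seeded from ``rng_seed``; two calls with the same seed
    produce byte-identical files.
    """
    from .mesosim import PhantomConfig, SimConfig, make_string_phantom, simulate_mesoscopy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    grid = GridSpec((96, 96, 128), (20.0, 20.0, 20.0))

    for i in range(n_lnets):
        cfg = small_lnet_config(rng_seed + i, grid)
        net = generate_lnet(cfg)
        gt = voxelize_network(net, grid)
        sim = simulate_mesoscopy(gt, SimConfig(rng_seed=rng_seed + i))
        base = out_dir / f"lnet_{i:02d}"
        outputs = [
            save_volume(gt, base.with_name(base.name + "_gt.tif"), scale_binary=True),
            save_volume(sim, base.with_name(base.name + "_sim.tif")),
            *write_network_csv(net, base),
        ]
        manifest.add_stage(f"lnet_{i:02d}", cfg, rng_seed + i, outputs=outputs)

    phantom_cfg = PhantomConfig(rng_seed=rng_seed)
    pv, pnet = make_string_phantom(phantom_cfg)
    outputs = [
        save_volume(pv, out_dir / "phantom_gt.tif", scale_binary=True),
        *write_network_csv(pnet, out_dir / "phantom"),
    ]
    manifest.add_stage("phantom", phantom_cfg, rng_seed, outputs=outputs)

    # degenerate cases: empty volume, single tube, looped network
    empty = VoxelVolume(np.zeros((32, 32, 32), dtype=np.uint8), (20.0, 20.0, 20.0))
    small_grid = GridSpec((96, 96, 96), (20.0, 20.0, 20.0))
    tube = voxelize_network(
        make_single_tube_network(length_mm=1.5, y_mm=0.96, depth_mm=0.5), small_grid
    )
    loop = voxelize_network(make_loop_network(), small_grid)
    outputs = [
        save_volume(empty, out_dir / "degenerate_empty.tif", scale_binary=True),
        save_volume(tube, out_dir / "degenerate_tube.tif", scale_binary=True),
        save_volume(loop, out_dir / "degenerate_loop.tif", scale_binary=True),
    ]
    manifest.add_stage("degenerate", None, rng_seed, outputs=outputs)
    manifest.save(out_dir / "manifest.json")
    return manifest
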