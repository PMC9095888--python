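"""Skeletonisation of binary vessel masks into axisymmetric tube graphs.

The mask is thinned to a one-voxel, 26-connected medial skeleton with a
homotopic 3D thinning algorithm (connected components and loops of the
digital object are preserved), radii are assigned from the Euclidean
distance transform in physical units, spurious terminal branches are pruned,
and the skeleton is decomposed into a branch-level graph: voxels with other
than two skeleton neighbours become nodes (junction voxels that touch are
merged into a single node), maximal degree-2 chains become edges carrying
ordered centerline polylines with per-point radii.

``estimate_tube_radii`` refits a single tube radius per branch from the mask
cross-section: the inscribed-sphere (distance-transform) radius when the
cross-section is consistent with a filled disc, or half the maximal
cross-sectional extent when the section is substantially larger than the
inscribed disc — the partially detected tube case (top-surface illumination),
where the detected crescent still spans the full vessel width.  This is what
makes tube-model volumes robust to partial illumination while plain voxel
counts underestimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skeletonize

from .vascgen import Branch
from .volume import VoxelVolume

__all__ = [
    "Skeleton",
    "VesselGraph",
    "skeletonize_mask",
    "prune_skeleton",
    "skeleton_to_graph",
    "estimate_tube_radii",
]

_NEIGH = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


@dataclass
class Skeleton:
    """Centerline voxel set with per-voxel radii (mm, physical units)."""

    voxels: np.ndarray  # (N, 3) int indices
    radii_mm: np.ndarray  # (N,)
    shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing_um, dtype=float) / 1000.0

    def coords_mm(self) -> np.ndarray:
        return self.voxels * self.spacing_mm + np.asarray(self.origin_mm)

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=np.uint8)
        if len(self):
            m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = 1
        return m


@dataclass
class VesselGraph:
    """Branch-level vascular graph extracted from a skeleton."""

    nodes: dict[int, dict]
    branches: list[Branch]
    branch_voxels: dict[int, np.ndarray] = field(default_factory=dict)
    spacing_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] | None = None

    def as_multigraph(self):
        import networkx as nx

        g = nx.MultiGraph()
        for nid, info in self.nodes.items():
            g.add_node(nid, **info)
        for b in self.branches:
            g.add_edge(b.start_node, b.end_node, key=b.id, branch=b, length=b.length_mm)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.branches)


def skeletonize_mask(mask: VoxelVolume) -> Skeleton:
    """Thin a binary mask to its medial skeleton and attach physical radii.

    Thinning preserves the homotopy type of the 26-connected digital object;
    radii come from the Euclidean distance transform of the mask with the
    anisotropic voxel spacing as sampling, so they are in mm.
    """
    bool_mask = mask.as_bool()
    if not bool_mask.any():
        warnings.warn("empty mask: returning an empty skeleton", stacklevel=2)
        return Skeleton(
            np.empty((0, 3), int), np.empty(0), bool_mask.shape, mask.spacing_um, mask.origin_mm
        )
    skel = _skeletonize(bool_mask)
    edt = ndimage.distance_transform_edt(bool_mask, sampling=mask.spacing_mm)
    voxels = np.argwhere(skel)
    radii = edt[skel]
    return Skeleton(voxels, radii, bool_mask.shape, mask.spacing_um, mask.origin_mm)


# ---------------------------------------------------------------------------
# Graph extraction
# ---------------------------------------------------------------------------


def _adjacency(voxels: np.ndarray) -> tuple[dict, list[list[int]]]:
    """26-neighbourhood adjacency among skeleton voxels, with redundant
    diagonal edges removed.

    A diagonal adjacency (2 or 3 differing coordinates) that merely
    duplicates a two-step path of lower-rank edges through a common
    neighbour is dropped: such triangle closures otherwise inflate junction
    degrees and read as spurious one-voxel loops, although the digital
    object has no hole there.  Edges are processed in decreasing rank so
    connectivity is never broken.
    """
    index = {tuple(v): i for i, v in enumerate(voxels)}
    neigh: list[set[int]] = [set() for _ in range(len(voxels))]
    rank: dict[tuple[int, int], int] = {}
    for i, v in enumerate(voxels):
        for off in _NEIGH:
            j = index.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None:
                neigh[i].add(j)
                if i < j:
                    rank[(i, j)] = int(np.count_nonzero(off))
    for r in (3, 2):
        for (a, b) in sorted(k for k, v in rank.items() if v == r):
            if b not in neigh[a]:
                continue
            for c in sorted(neigh[a] & neigh[b]):
                ra = rank[(min(a, c), max(a, c))]
                rb = rank[(min(b, c), max(b, c))]
                if ra < r and rb < r:
                    neigh[a].discard(b)
                    neigh[b].discard(a)
                    break
    return index, [sorted(s) for s in neigh]


def skeleton_to_graph(skeleton: Skeleton) -> VesselGraph:
    """Decompose a skeleton into junction/endpoint nodes and branch edges.

    Voxels with a number of skeleton neighbours other than two are node
    voxels; mutually adjacent node voxels merge into a single node (thinning
    can leave small junction clusters).  Maximal chains of degree-2 voxels
    become edges.  Components that are pure cycles (every voxel degree 2)
    keep one anchor node carrying a self-loop edge, so the graph's Betti
    numbers match the skeleton's.
    """
    voxels = skeleton.voxels
    radii = skeleton.radii_mm
    spacing = skeleton.spacing_mm
    origin = np.asarray(skeleton.origin_mm)
    if len(voxels) == 0:
        return VesselGraph({}, [], {}, skeleton.spacing_um, skeleton.origin_mm, skeleton.shape)

    _, neigh = _adjacency(voxels)
    degree = np.array([len(n) for n in neigh])
    is_node = degree != 2

    # pure-cycle components: anchor at the smallest voxel id
    seen = np.zeros(len(voxels), dtype=bool)
    for i in range(len(voxels)):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for j in neigh[cur]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        if not any(is_node[c] for c in comp):
            is_node[min(comp)] = True

    # merge touching node voxels into clusters
    cluster_of = np.full(len(voxels), -1)
    clusters: list[list[int]] = []
    for i in np.flatnonzero(is_node):
        if cluster_of[i] >= 0:
            continue
        cid = len(clusters)
        members, stack = [], [i]
        cluster_of[i] = cid
        while stack:
            cur = stack.pop()
            members.append(cur)
            for j in neigh[cur]:
                if is_node[j] and cluster_of[j] < 0:
                    cluster_of[j] = cid
                    stack.append(j)
        clusters.append(sorted(members))

    nodes: dict[int, dict] = {}
    for cid, members in enumerate(clusters):
        pos = (voxels[members] * spacing + origin).mean(axis=0)
        nodes[cid] = {
            "position": pos,
            "voxels": voxels[members],
            "radius_mm": float(np.max(radii[members])),
        }

    branches: list[Branch] = []
    branch_voxels: dict[int, np.ndarray] = {}
    chain_used = np.zeros(len(voxels), dtype=bool)

    def add_branch(path: list[int], c_start: int, c_end: int) -> None:
        bid = len(branches)
        pts = voxels[path] * spacing + origin
        branches.append(Branch(bid, c_start, c_end, pts, radii[path]))
        branch_voxels[bid] = voxels[path]

    for cid, members in enumerate(clusters):
        for m in members:
            for nb in sorted(neigh[m]):
                if is_node[nb]:
                    continue  # intra/inter-cluster hops carry no chain
                if chain_used[nb]:
                    continue
                path = [m, nb]
                chain_used[nb] = True
                prev, cur = m, nb
                while not is_node[cur]:
                    nxt = [j for j in neigh[cur] if j != prev and (is_node[j] or not chain_used[j])]
                    if not nxt:
                        break  # dangling chain end (shouldn't happen off-degree bookkeeping)
                    step = sorted(nxt)[0]
                    path.append(step)
                    if not is_node[step]:
                        chain_used[step] = True
                    prev, cur = cur, step
                add_branch(path, cid, cluster_of[cur] if is_node[cur] else cid)
        # direct adjacency between two voxels of *different* clusters cannot
        # occur (clusters are maximal), but a cluster may be linked to a
        # neighbouring chainless cluster in degenerate masks; nothing to do.

    # node degrees from incident edges (isolated voxels stay degree 0)
    for cid in nodes:
        nodes[cid]["degree"] = 0
    for b in branches:
        nodes[b.start_node]["degree"] += 1
        nodes[b.end_node]["degree"] += 1

    return VesselGraph(
        nodes, branches, branch_voxels, skeleton.spacing_um, skeleton.origin_mm, skeleton.shape
    )


def prune_skeleton(skeleton: Skeleton, min_branch_length_mm: float | None = None) -> Skeleton:
    """Iteratively remove short terminal branches (thinning artefacts).

    A terminal branch (one endpoint of degree 1 attached to a junction of
    degree >= 3) is removed when shorter than
    ``max(min_branch_length_mm, 2 x junction radius)``; the default floor is
    40 µm.  Loops are never broken and isolated paths are never removed, so
    the homotopy type is preserved.
    """
    floor = 0.040 if min_branch_length_mm is None else float(min_branch_length_mm)
    current = skeleton
    while True:
        graph = skeleton_to_graph(current)
        if not graph.branches:
            return current
        degree = {nid: info.get("degree", 0) for nid, info in graph.nodes.items()}
        removed = []
        for b in graph.branches:
            if b.start_node == b.end_node:
                continue  # self-loop: never prune
            d_s, d_e = degree[b.start_node], degree[b.end_node]
            if 1 in (d_s, d_e) and max(d_s, d_e) >= 3:
                junction = b.start_node if d_s >= 3 else b.end_node
                local_r = graph.nodes[junction]["radius_mm"]
                if b.length_mm < max(floor, 2.0 * local_r):
                    removed.append(b.id)
        if not removed:
            return current
        keep_voxels = []
        keep_radii = []
        removed_set = set(removed)
        vox_index = {tuple(v): i for i, v in enumerate(current.voxels)}
        kept = np.zeros(len(current.voxels), dtype=bool)
        for b in graph.branches:
            vox = graph.branch_voxels[b.id]
            if b.id in removed_set:
                vox = vox[:1] if degree[b.start_node] >= 3 else vox[-1:]
                # keep only the junction-side voxel (it belongs to the node)
            for v in vox:
                kept[vox_index[tuple(v)]] = True
        # node voxels always survive
        for info in graph.nodes.values():
            for v in info["voxels"]:
                kept[vox_index[tuple(v)]] = True
        # drop node voxels that belonged exclusively to removed endpoint tips
        tip_nodes = set()
        for b in graph.branches:
            if b.id in removed_set:
                tip = b.start_node if degree[b.start_node] == 1 else b.end_node
                tip_nodes.add(tip)
        for tip in tip_nodes:
            if degree[tip] == 1:
                for v in graph.nodes[tip]["voxels"]:
                    kept[vox_index[tuple(v)]] = False
        current = Skeleton(
            current.voxels[kept],
            current.radii_mm[kept],
            current.shape,
            current.spacing_um,
            current.origin_mm,
        )


# ---------------------------------------------------------------------------
# Axisymmetric tube radius refit
# ---------------------------------------------------------------------------


def _orthonormal_plane(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / (np.linalg.norm(tangent) + 1e-12)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def estimate_tube_radii(
    graph: VesselGraph,
    mask: VoxelVolume,
    sample_every: int = 3,
    area_ratio: float = 1.5,
) -> VesselGraph:
    """Refit one tube radius per branch from mask cross-sections.

    For sampled interior centerline points, the mask cross-section in the
    plane orthogonal to the local tangent is measured: its area ``A`` and
    maximal extent (Feret diameter).  If ``A`` is consistent with the disc
    of the inscribed (distance-transform) radius, that radius is kept;
    if ``A`` exceeds it by more than ``area_ratio``, the cross-section is a
    partial tube and the radius is taken as half the maximal extent instead.
    Branch radii are replaced by the single fitted value.
    """
    data = mask.as_bool()
    spacing = mask.spacing_mm
    origin = np.asarray(mask.origin_mm)
    step = float(spacing.min()) / 2.0
    shape = np.asarray(data.shape)
    new_branches: list[Branch] = []
    for b in graph.branches:
        pts = b.points
        r_edt = float(np.median(b.radii))
        if len(pts) < 2 or r_edt <= 0:
            new_branches.append(Branch(b.id, b.start_node, b.end_node, pts.copy(), b.radii.copy()))
            continue
        interior = np.arange(1, len(pts) - 1) if len(pts) > 4 else np.arange(len(pts))
        samples = interior[:: max(sample_every, 1)]
        half = max(4.0 * r_edt, 8.0 * step)
        n = int(np.ceil(half / step))
        offs = np.arange(-n, n + 1) * step
        gu, gv = np.meshgrid(offs, offs, indexing="ij")
        areas, ferets, inscribed = [], [], []
        for si in samples:
            i0, i1 = max(si - 1, 0), min(si + 1, len(pts) - 1)
            tangent = pts[i1] - pts[i0]
            if np.linalg.norm(tangent) < 1e-9:
                continue
            u, v = _orthonormal_plane(tangent)
            plane_pts = pts[si] + gu[..., None] * u + gv[..., None] * v
            idx = np.round((plane_pts - origin) / spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=-1)
            patch = np.zeros(gu.shape, dtype=bool)
            patch[ok] = data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            if not patch[n, n]:
                continue
            lab, _ = ndimage.label(patch, structure=np.ones((3, 3), dtype=bool))
            comp = lab == lab[n, n]
            areas.append(comp.sum() * step * step)
            edt2d = ndimage.distance_transform_edt(comp, sampling=step)
            inscribed.append(float(edt2d.max()))
            # width = extent along the section's principal axis (robust to the
            # diagonal inflation a pairwise Feret picks up on crescents)
            cpts = np.stack([gu[comp], gv[comp]], axis=1)
            centred = cpts - cpts.mean(axis=0)
            if len(cpts) > 2:
                _, vecs = np.linalg.eigh(centred.T @ centred)
                proj = centred @ vecs[:, -1]
            else:
                proj = centred[:, 0]
            ferets.append(float(proj.max() - proj.min()))
        if not areas:
            r_fit = r_edt
        else:
            med_area = float(np.median(areas))
            med_feret = float(np.median(ferets))
            med_insc = float(np.median(inscribed))
            # A filled-disc cross-section has area ~ pi * r_inscribed^2; a
            # substantially larger area means a partially detected tube whose
            # width (Feret extent) still spans the full vessel diameter.
            if med_area > area_ratio * np.pi * med_insc**2 and med_feret / 2.0 > med_insc:
                r_fit = med_feret / 2.0
            else:
                r_fit = max(r_edt, med_insc)
        new_branches.append(
            Branch(b.id, b.start_node, b.end_node, pts.copy(), np.full(len(pts), r_fit))
        )
    return VesselGraph(
        {k: dict(v) for k, v in graph.nodes.items()},
        new_branches,
        dict(graph.branch_voxels),
        graph.spacing_um,
        graph.origin_mm,
        graph.shape,
    )
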