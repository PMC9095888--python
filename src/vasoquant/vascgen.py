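"""Stochastic synthetic vascular networks ("L-nets") and their rasterization.

A Lindenmayer system (L-system) rewrites an axiom string with stochastic
productions; the resulting string is interpreted by a 3D turtle whose ``F``
moves draw tubular segments.  The turtle output is assembled into a spatial
graph (:class:`VesselNetwork`) with per-branch centerline polylines and radii,
which serves as fully known ground truth: geometry (diameters, lengths),
topology (connected components, loops) and blood volume are all analytic.

Rasterization draws every centerline with a 3D Bresenham line (26-connected
voxel chains) and then fills each vessel with all voxels whose centre lies
within the local radius, yielding a binary ground-truth volume on an
arbitrary (possibly anisotropic) grid.

Turtle alphabet
---------------
``F``  draw a segment (length sampled per ``segment_length``),
``+``/``-``  yaw left/right, ``&``/``^``  pitch down/up,
``/``/``\\``  roll, ``[``  push state and start a child branch (radius reduced
by the Murray-law factor), ``]``  pop state.  All other symbols are inert and
may be used as placeholders in grammars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import GridSpec, VoxelVolume

__all__ = [
    "GrammarConfig",
    "VesselNetwork",
    "Branch",
    "generate_lnet",
    "voxelize_network",
    "network_ground_truth_descriptors",
    "bresenham_line_3d",
    "DEFAULT_PRODUCTIONS",
]


class ConfigurationError(ValueError):
    """Raised for invalid grammar or simulation configuration."""


#: Default stochastic grammar: a bifurcating rule dominates, with occasional
#: single side branches, plain elongation, and out-of-plane (pitched) splits
#: so networks are genuinely three-dimensional.
DEFAULT_PRODUCTIONS: list[tuple[str, str, float]] = [
    ("F", "F[+F][-F]", 0.40),
    ("F", "F[&+F][^-F]", 0.25),
    ("F", "F[+&F]", 0.15),
    ("F", "FF", 0.10),
    ("F", "F", 0.10),
]


@dataclass
class GrammarConfig:
    """Configuration of the stochastic L-system and turtle interpretation.

    Angles are in degrees, lengths/positions in mm.  ``radius_decay`` is the
    Murray-law exponent ``g`` in ``r_parent**g = sum(r_child**g)``; each
    bracketed child takes ``r * 2**(-1/g)`` (symmetric bifurcation).
    """

    axiom: str = "F"
    productions: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_PRODUCTIONS)
    )
    iterations: int = 6
    root_position: tuple[float, float, float] = (5.12, 5.12, 0.0)
    initial_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    initial_radius: float = 0.12
    branch_angle_deg: tuple[float, float] = (35.0, 8.0)
    segment_length: tuple[float, float] = (0.40, 0.08)
    radius_decay: float = 3.0
    min_radius: float = 0.015
    domain_box: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.0, 0.0),
        (10.24, 10.24, 2.80),
    )
    rng_seed: int = 0

    def validate(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.initial_radius <= 0:
            raise ConfigurationError("initial_radius must be > 0")
        if self.radius_decay <= 0:
            raise ConfigurationError("radius_decay must be > 0")
        preds = {p for p, _, _ in self.productions}
        for pred in preds:
            total = sum(w for p, _, w in self.productions if p == pred)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigurationError(
                    f"production probabilities for {pred!r} sum to {total}, expected 1"
                )
        lo, hi = np.asarray(self.domain_box[0]), np.asarray(self.domain_box[1])
        if np.any(hi <= lo):
            raise ConfigurationError("domain_box upper corner must exceed lower corner")


@dataclass
class Branch:
    """One vessel branch: an ordered centerline polyline with per-point radii."""

    id: int
    start_node: int
    end_node: int
    points: np.ndarray  # (N, 3) mm
    radii: np.ndarray  # (N,) mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.radii.size == 1:
            self.radii = np.full(len(self.points), float(self.radii[0]))
        if len(self.radii) != len(self.points):
            raise ValueError("radii must have one value per polyline point")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def mean_radius_mm(self) -> float:
        return float(self.radii.mean())

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.mean_radius_mm


@dataclass
class VesselNetwork:
    """Ground-truth branching network: nodes, branches, and the domain box."""

    nodes: dict[int, np.ndarray]
    branches: list[Branch]
    domain_box: tuple[tuple[float, float, float], tuple[float, float, float]]
    clipped_branches: int = 0

    def as_multigraph(self):
        import networkx as nx

        g = nx.MultiGraph()
        for nid, pos in self.nodes.items():
            g.add_node(nid, position=np.asarray(pos))
        for b in self.branches:
            g.add_edge(b.start_node, b.end_node, key=b.id, branch=b, length=b.length_mm)
        return g

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def total_length_mm(self) -> float:
        return sum(b.length_mm for b in self.branches)

    def total_volume_mm3(self) -> float:
        """Analytic blood volume: sum of pi * r_bar^2 * ds over polyline steps."""
        total = 0.0
        for b in self.branches:
            ds = np.linalg.norm(np.diff(b.points, axis=0), axis=1)
            rbar = 0.5 * (b.radii[:-1] + b.radii[1:])
            total += float(np.sum(np.pi * rbar**2 * ds))
        return total


# ---------------------------------------------------------------------------
# L-system rewriting and turtle interpretation
# ---------------------------------------------------------------------------


def rewrite(axiom: str, productions, iterations: int, rng: np.random.Generator) -> str:
    """Apply stochastic parallel rewriting for ``iterations`` rounds."""
    table: dict[str, list[tuple[str, float]]] = {}
    for pred, succ, w in productions:
        table.setdefault(pred, []).append((succ, float(w)))
    s = axiom
    for _ in range(iterations):
        out = []
        for ch in s:
            rules = table.get(ch)
            if not rules:
                out.append(ch)
                continue
            weights = np.array([w for _, w in rules])
            pick = rng.choice(len(rules), p=weights / weights.sum())
            out.append(rules[pick][0])
        s = "".join(out)
    return s


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _clip_segment_to_box(p0, p1, lo, hi):
    """Return (end point, clipped?) for the segment p0->p1 against the box.

    p0 is assumed inside; if p1 lies outside, the exit point on the boundary
    is returned.
    """
    d = p1 - p0
    t = 1.0
    for ax in range(3):
        if d[ax] > 0 and p1[ax] > hi[ax]:
            t = min(t, (hi[ax] - p0[ax]) / d[ax])
        elif d[ax] < 0 and p1[ax] < lo[ax]:
            t = min(t, (lo[ax] - p0[ax]) / d[ax])
    if t >= 1.0:
        return p1, False
    return p0 + max(t, 0.0) * d, True


@dataclass
class _TurtleState:
    position: np.ndarray
    frame: np.ndarray  # rows: heading, left, up
    radius: float
    node: int  # id of the network node at the current position
    dead: bool  # set once the turtle exits the domain box


def generate_lnet(config: GrammarConfig) -> VesselNetwork:
    """Generate a stochastic vascular network from an L-system grammar.

    The returned network is connected (a tree rooted at ``root_position``)
    and fully deterministic given ``(config, rng_seed)``.  Branches whose
    geometry would leave ``domain_box`` are truncated at the boundary and
    counted in ``VesselNetwork.clipped_branches``; the turtle does not draw
    beyond a clipped segment, so connectivity is preserved.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    s = rewrite(config.axiom, config.productions, config.iterations, rng)

    lo = np.asarray(config.domain_box[0], dtype=float)
    hi = np.asarray(config.domain_box[1], dtype=float)

    heading = np.asarray(config.initial_direction, dtype=float)
    heading = heading / np.linalg.norm(heading)
    # Build an orthonormal frame around the heading.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, heading)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    left = np.cross(heading, ref)
    left /= np.linalg.norm(left)
    up = np.cross(heading, left)
    frame = np.vstack([heading, left, up])

    # Node bookkeeping with coordinate-keyed de-duplication so coincident
    # segments produced by the rewriting collapse onto shared nodes/branches.
    nodes: dict[int, np.ndarray] = {}
    node_key: dict[tuple, int] = {}
    segments: dict[tuple, tuple[int, int, float]] = {}  # (na, nb) key -> seg
    clipped = 0

    def get_node(pos: np.ndarray) -> int:
        key = tuple(np.round(pos, 9))
        if key not in node_key:
            nid = len(nodes)
            node_key[key] = nid
            nodes[nid] = pos.copy()
        return node_key[key]

    root = np.asarray(config.root_position, dtype=float)
    state = _TurtleState(root, frame, float(config.initial_radius), get_node(root), False)
    stack: list[_TurtleState] = []

    mean_ang, sd_ang = config.branch_angle_deg
    mean_len, sd_len = config.segment_length
    child_factor = 0.5 ** (1.0 / config.radius_decay)

    def sample_angle() -> float:
        return np.deg2rad(rng.normal(mean_ang, sd_ang))

    for ch in s:
        if ch == "F":
            length = rng.normal(mean_len, sd_len)
            length = max(length, 0.05 * mean_len)
            if state.dead:
                continue
            end = state.position + length * state.frame[0]
            end, was_clipped = _clip_segment_to_box(state.position, end, lo, hi)
            if was_clipped:
                clipped += 1
                state.dead = True
            if np.linalg.norm(end - state.position) < 1e-9:
                continue
            na, nb = state.node, get_node(end)
            key = (min(na, nb), max(na, nb))
            if key not in segments:
                segments[key] = (na, nb, state.radius)
            state.position = end
            state.node = nb
        elif ch in "+-":
            ang = sample_angle() * (1 if ch == "+" else -1)
            state.frame = (_rotation(state.frame[2], ang) @ state.frame.T).T
        elif ch in "&^":
            ang = sample_angle() * (1 if ch == "&" else -1)
            state.frame = (_rotation(state.frame[1], ang) @ state.frame.T).T
        elif ch in "/\\":
            ang = sample_angle() * (1 if ch == "/" else -1)
            state.frame = (_rotation(state.frame[0], ang) @ state.frame.T).T
        elif ch == "[":
            stack.append(
                _TurtleState(
                    state.position.copy(), state.frame.copy(), state.radius, state.node, state.dead
                )
            )
            state.radius = max(state.radius * child_factor, config.min_radius)
        elif ch == "]":
            if not stack:
                raise ConfigurationError("unbalanced ']' in generated string")
            state = stack.pop()
        # other symbols are inert

    branches = [
        Branch(i, na, nb, np.vstack([nodes[na], nodes[nb]]), np.array([r, r]))
        for i, ((_, _), (na, nb, r)) in enumerate(sorted(segments.items()))
    ]
    net = VesselNetwork(nodes, branches, config.domain_box, clipped_branches=clipped)
    return _merge_degree2_chains(net)


def _merge_degree2_chains(net: VesselNetwork) -> VesselNetwork:
    """Fuse maximal chains through degree-2 nodes into single branches.

    Consecutive ``F`` segments (e.g. from an ``F -> FF`` elongation rule)
    belong to one vessel; only endpoints and junctions remain as nodes.
    """
    import networkx as nx

    g = net.as_multigraph()
    keep = {n for n in g.nodes if g.degree(n) != 2}
    # components that are pure cycles keep an arbitrary anchor node
    for comp in nx.connected_components(g):
        if not comp & keep:
            keep.add(min(comp))

    new_branches: list[Branch] = []
    visited_edges = set()

    def edge_id(u, v, k):
        return (min(u, v), max(u, v), k)

    for start in sorted(keep):
        for _, nbr, key in sorted(g.edges(start, keys=True)):
            if edge_id(start, nbr, key) in visited_edges:
                continue
            # walk the chain until the next kept node
            chain_pts = [g.nodes[start]["position"]]
            chain_radii = []
            u, v, k = start, nbr, key
            while True:
                visited_edges.add(edge_id(u, v, k))
                br: Branch = g.edges[u, v, k]["branch"]
                pts = br.points if br.start_node == u else br.points[::-1]
                rad = br.radii if br.start_node == u else br.radii[::-1]
                if not chain_radii:
                    chain_radii.append(float(rad[0]))
                chain_pts.extend(pts[1:])
                chain_radii.extend(float(r) for r in rad[1:])
                if v in keep:
                    break
                nxt = [
                    (v, w, kk)
                    for _, w, kk in g.edges(v, keys=True)
                    if edge_id(v, w, kk) not in visited_edges
                ]
                if not nxt:
                    break
                u, v, k = nxt[0]
            new_branches.append(
                Branch(
                    len(new_branches),
                    start,
                    v,
                    np.vstack(chain_pts),
                    np.asarray(chain_radii),
                )
            )
    used_nodes = {b.start_node for b in new_branches} | {b.end_node for b in new_branches}
    nodes = {n: net.nodes[n] for n in used_nodes}
    return VesselNetwork(nodes, new_branches, net.domain_box, net.clipped_branches)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def bresenham_line_3d(p0, p1) -> np.ndarray:
    """Integer 3D Bresenham line from voxel ``p0`` to ``p1`` (inclusive).

    The chain is 26-connected (steps may advance several axes at once) and
    contains ``max(|delta|) + 1`` voxels.
    """
    p0 = np.asarray(p0, dtype=int)
    p1 = np.asarray(p1, dtype=int)
    d = np.abs(p1 - p0)
    step = np.sign(p1 - p0)
    n = int(d.max())
    if n == 0:
        return p0.reshape(1, 3)
    primary = int(np.argmax(d))
    others = [ax for ax in range(3) if ax != primary]
    err = [2 * d[ax] - d[primary] for ax in others]
    out = np.empty((n + 1, 3), dtype=int)
    cur = p0.copy()
    out[0] = cur
    for i in range(n):
        cur[primary] += step[primary]
        for j, ax in enumerate(others):
            if err[j] > 0:
                cur[ax] += step[ax]
                err[j] -= 2 * d[primary]
            err[j] += 2 * d[ax]
        out[i + 1] = cur
    return out


def _ball_offsets(radius_mm: float, spacing_mm: np.ndarray) -> np.ndarray:
    """Voxel offsets whose centre lies within ``radius_mm`` of the origin."""
    half = np.maximum(np.floor(radius_mm / spacing_mm).astype(int), 0)
    axes = [np.arange(-h, h + 1) for h in half]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    d2 = (gx * spacing_mm[0]) ** 2 + (gy * spacing_mm[1]) ** 2 + (gz * spacing_mm[2]) ** 2
    sel = d2 <= radius_mm**2 + 1e-12
    return np.stack([gx[sel], gy[sel], gz[sel]], axis=1)


def voxelize_network(network: VesselNetwork, grid: GridSpec) -> VoxelVolume:
    """Rasterize a network into a binary ground-truth volume.

    Centerlines become 26-connected Bresenham voxel chains; every voxel whose
    centre lies within the local radius (physical units, anisotropy-aware) of
    the centerline is set.  Deterministic.
    """
    spacing_mm = grid.spacing_mm
    min_radius = float(min(b.radii.min() for b in network.branches)) if network.branches else 0.0
    if network.branches and min_radius < 0.5 * spacing_mm.max():
        warnings.warn(
            "smallest vessel radius is below half the largest voxel spacing; "
            "rasterized structure may be discontinuous",
            stacklevel=2,
        )
    vol = np.zeros(grid.shape, dtype=np.uint8)
    shape = np.asarray(grid.shape)
    ball_cache: dict[float, np.ndarray] = {}

    for b in network.branches:
        idx = grid.world_to_index(b.points)
        ivox = np.round(idx).astype(int)
        # centerline chain
        chain_parts = [
            bresenham_line_3d(ivox[i], ivox[i + 1]) for i in range(len(ivox) - 1)
        ]
        chain = np.vstack(chain_parts) if chain_parts else ivox
        inb = np.all((chain >= 0) & (chain < shape), axis=1)
        chain = chain[inb]
        if chain.size:
            vol[chain[:, 0], chain[:, 1], chain[:, 2]] = 1
        # dense resampling of the polyline so the tube surface is smooth
        step = 0.5 * spacing_mm.min()
        for i in range(len(b.points) - 1):
            p0, p1 = b.points[i], b.points[i + 1]
            seg_len = np.linalg.norm(p1 - p0)
            nsamp = max(int(np.ceil(seg_len / step)), 1)
            t = np.linspace(0.0, 1.0, nsamp + 1)
            samples = p0 + t[:, None] * (p1 - p0)
            radii = b.radii[i] + t * (b.radii[i + 1] - b.radii[i])
            for pt, r in zip(samples, radii):
                rkey = round(float(r), 6)
                if rkey not in ball_cache:
                    ball_cache[rkey] = _ball_offsets(rkey, spacing_mm)
                offs = ball_cache[rkey]
                centre = np.round(grid.world_to_index(pt)[0]).astype(int)
                vox = centre + offs
                ok = np.all((vox >= 0) & (vox < shape), axis=1)
                vox = vox[ok]
                if vox.size:
                    vol[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
    return VoxelVolume(vol, grid.spacing_um, grid.origin_mm)


def network_ground_truth_descriptors(network: VesselNetwork):
    """Descriptors computed directly from the analytic network polylines.

    Same :class:`~vasoquant.descriptors.DescriptorSet` as the image-derived
    path, but free of any rasterization/skeletonisation error — the oracle
    each processed network is compared against.
    """
    from . import descriptors as d

    if not network.branches:
        raise ValueError("cannot compute descriptors of an empty network")
    return d.describe(network)
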