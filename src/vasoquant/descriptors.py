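"""Statistical and topological descriptors of vascular networks.

Per-branch: length (polyline arc length, mm), diameter (twice the mean
per-point radius, mm), tortuosity as the sum-of-angles measure (SOAM,
rad/mm) and curvature as the chord-to-length ratio (CLR, dimensionless in
(0, 1], 1 for straight vessels).

Per-network: the Betti numbers — beta0, the number of connected components
(subnetworks), and beta1, the number of independent loops (1D holes) of the
branch graph, via the Euler relation ``beta1 = E - V + beta0`` — the number
of edges and nodes, and the tube-model blood volume ``sum(pi r^2 ds)``.

Works on anything exposing ``.branches`` (objects with ``points``/``radii``)
and ``.as_multigraph()``: both the analytic ground-truth networks and
image-derived skeleton graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorSet",
    "branch_statistics",
    "soam",
    "clr",
    "betti_numbers",
    "skeleton_blood_volume",
    "describe",
]


@dataclass
class DescriptorSet:
    """Per-branch table plus network-level summary of vascular descriptors."""

    branch_table: pd.DataFrame
    summary: dict

    def __getitem__(self, key: str):
        return self.summary[key]

    def to_json(self) -> dict:
        return {
            "summary": {k: (float(v) if np.isscalar(v) else v) for k, v in self.summary.items()},
            "branches": self.branch_table.to_dict(orient="records"),
        }

    def to_csv(self, path) -> None:
        self.branch_table.to_csv(path, index=False)


def _arc_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def soam(points: np.ndarray, in_plane_only: bool = False) -> float:
    """Sum-of-angles tortuosity of a centerline polyline, in rad/mm.

    At every interior point the in-plane (curvature) angle between
    consecutive step vectors is combined with the torsional angle between
    consecutive osculating-plane normals as the total angle
    ``sqrt(IP^2 + TP^2)``; the angle sum is normalised by the total path
    length.  Straight lines score 0.  ``in_plane_only`` drops the torsional
    term.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        warnings.warn("SOAM needs at least 3 points; returning 0", stacklevel=2)
        return 0.0
    t = np.diff(pts, axis=0)
    norms = np.linalg.norm(t, axis=1)
    keep = norms > 1e-12
    t, norms = t[keep], norms[keep]
    if len(t) < 2:
        return 0.0
    unit = t / norms[:, None]
    length = float(norms.sum())
    # in-plane angles at each interior point
    cos_ip = np.clip(np.einsum("ij,ij->i", unit[:-1], unit[1:]), -1.0, 1.0)
    ip = np.arccos(cos_ip)
    if in_plane_only:
        return float(ip.sum() / length)
    # torsional angles between consecutive binormals T_{k-1} x T_k
    binormals = np.cross(unit[:-1], unit[1:])
    bn = np.linalg.norm(binormals, axis=1)
    tp = np.zeros_like(ip)
    if len(binormals) >= 2:
        valid = (bn[:-1] > 1e-9) & (bn[1:] > 1e-9)
        b0 = binormals[:-1][valid] / bn[:-1][valid][:, None]
        b1 = binormals[1:][valid] / bn[1:][valid][:, None]
        cos_tp = np.clip(np.einsum("ij,ij->i", b0, b1), -1.0, 1.0)
        tp_valid = np.arccos(cos_tp)
        # torsion is attributed to the interior point shared by both angles
        tp_full = np.zeros(len(binormals) - 1)
        tp_full[valid] = tp_valid
        tp[: len(tp_full)] += tp_full
    total = np.sqrt(ip**2 + tp**2).sum()
    return float(total / length)


def clr(points: np.ndarray) -> float:
    """Chord-to-length ratio: endpoint distance / arc length, in (0, 1]."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("CLR needs at least 2 points")
    arc = _arc_length(pts)
    if arc <= 0:
        raise ValueError("zero-length branch has no chord-to-length ratio")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    value = chord / arc
    if value < 1e-9:
        warnings.warn("closed-loop branch: coincident endpoints give CLR ~ 0", stacklevel=2)
    return value


def betti_numbers(graph) -> tuple[int, int]:
    """(beta0, beta1) of a vascular graph.

    ``beta0`` is the number of connected components; ``beta1`` follows from
    the Euler relation summed over components: ``E_c - V_c + 1`` each.
    Accepts a networkx (multi)graph or an object with ``as_multigraph``.
    """
    import networkx as nx

    g = graph.as_multigraph() if hasattr(graph, "as_multigraph") else graph
    if g.number_of_nodes() == 0:
        return 0, 0
    b0 = nx.number_connected_components(g)
    b1 = g.number_of_edges() - g.number_of_nodes() + b0
    return int(b0), int(b1)


def skeleton_blood_volume(graph) -> float:
    """Tube-model blood volume (mm^3): ``sum(pi * rbar^2 * ds)`` per step.

    ``rbar`` is the mean of the step-endpoint radii.  Raises when radii are
    missing.
    """
    total = 0.0
    for b in graph.branches:
        if b.radii is None or len(b.radii) != len(b.points):
            raise ValueError(f"branch {b.id} has no per-point radii")
        ds = np.linalg.norm(np.diff(b.points, axis=0), axis=1)
        rbar = 0.5 * (b.radii[:-1] + b.radii[1:])
        total += float(np.sum(np.pi * rbar**2 * ds))
    return total


def branch_statistics(graph) -> pd.DataFrame:
    """Per-branch diameters (2 x mean radius) and arc lengths, in mm."""
    rows = []
    for b in graph.branches:
        rows.append(
            {
                "branch_id": b.id,
                "length_mm": _arc_length(b.points),
                "diameter_mm": 2.0 * float(np.mean(b.radii)),
            }
        )
    return pd.DataFrame(rows, columns=["branch_id", "length_mm", "diameter_mm"])


def describe(graph, roi_volume_mm3: float | None = None) -> DescriptorSet:
    """Full descriptor set of a network or skeleton graph.

    ``roi_volume_mm3`` adds beta0/beta1 and blood volume normalised by the
    analysed region volume.
    """
    table = branch_statistics(graph)
    if len(table) == 0:
        raise ValueError("cannot describe an empty graph")
    soams, clrs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in graph.branches:
            soams.append(soam(b.points))
            clrs.append(clr(b.points) if _arc_length(b.points) > 0 else np.nan)
    table = table.assign(soam_rad_per_mm=soams, clr=clrs)
    b0, b1 = betti_numbers(graph)
    g = graph.as_multigraph()
    summary = {
        "beta0": b0,
        "beta1": b1,
        "n_edges": g.number_of_edges(),
        "n_nodes": g.number_of_nodes(),
        "total_length_mm": float(table["length_mm"].sum()),
        "median_length_mm": float(table["length_mm"].median()),
        "median_diameter_mm": float(table["diameter_mm"].median()),
        "median_soam_rad_per_mm": float(np.nanmedian(soams)),
        "median_clr": float(np.nanmedian(clrs)),
        "blood_volume_mm3": skeleton_blood_volume(graph),
    }
    if roi_volume_mm3:
        summary["beta0_per_mm3"] = b0 / roi_volume_mm3
        summary["beta1_per_mm3"] = b1 / roi_volume_mm3
        summary["blood_volume_fraction"] = summary["blood_volume_mm3"] / roi_volume_mm3
    return DescriptorSet(table, summary)
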