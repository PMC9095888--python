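"""Voxel-grid containers shared by the whole pipeline.

Conventions (used everywhere in :mod:`vasoquant`):

* Arrays are indexed ``[x, y, z]`` with the **depth axis last**; ``z = 0`` is
  the illumination surface and depth increases with the index.
* World coordinates are in **millimetres**; voxel spacing is stored in
  **micrometres** per axis.
* Voxel ``i`` along an axis is centred at ``origin + i * spacing`` (node
  centred), so a structure at depth 0.5 mm on a 20 µm grid sits on slice 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "VoxelVolume"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid: shape, per-axis spacing and world origin.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``; depth is the last axis.
    spacing_um
        Voxel spacing per axis in micrometres, e.g. ``(20, 20, 20)`` for the
        simulation grid or ``(20, 20, 4)`` for reconstructed in vivo stacks.
    origin_mm
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be three positive values (um), got {self.spacing_um}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing_um, dtype=float) / 1000.0

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent per axis (mm): ``shape * spacing``."""
        return np.asarray(self.shape, dtype=float) * self.spacing_mm

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / self.spacing_mm

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world coordinates (mm)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * self.spacing_mm + np.asarray(self.origin_mm)


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical metadata.

    Carries grayscale images, binary masks and label maps alike; ``data`` is
    indexed ``[x, y, z]`` with depth last.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be positive, got {self.spacing_um}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.spacing_um, self.origin_mm)

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing_um, dtype=float) / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def depth_coords_mm(self) -> np.ndarray:
        """World depth (mm) of every z-slice."""
        return self.origin_mm[2] + np.arange(self.data.shape[2]) * self.spacing_mm[2]

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1, 255)).all())

    def as_bool(self) -> np.ndarray:
        return self.data > 0

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        """Copy of the volume with the same geometry but new voxel data."""
        return VoxelVolume(data, self.spacing_um, self.origin_mm, dict(self.meta))

    def foreground_volume_mm3(self) -> float:
        """Volume of the nonzero voxels (mm^3)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3
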