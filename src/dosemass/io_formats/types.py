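"""Core spatial data types.

Conventions
-----------
* Arrays are indexed ``[ix, iy, iz]`` so that axis 0 is the patient x axis.
* The patient frame is axis-aligned LPS: +x = patient left, +y = posterior,
  +z = superior.  "Anterior" displacement is therefore -y and "caudal" is -z.
* World position of voxel center ``(ix, iy, iz)`` is
  ``origin + index * spacing`` (mm).  Oblique orientations are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from ..errors import ContourParseError, DataError, GeometryError

#: Allowed semantic unit tags for a :class:`VoxelGrid`.
ALLOWED_UNITS = ("HU", "g/cm3", "Gy", "1")

_GEOM_ATOL = 1e-6


@dataclass
class VoxelGrid:
    """A 3-D scalar volume with physical geometry.

    Parameters
    ----------
    values
        3-D array, shape ``(nx, ny, nz)``.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        World position of the center of voxel ``(0, 0, 0)`` in mm (LPS).
    unit
        Semantic tag: ``"HU"``, ``"g/cm3"``, ``"Gy"`` or ``"1"``.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "1"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise GeometryError("values must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.unit not in ALLOWED_UNITS:
            raise GeometryError(f"unit {self.unit!r} not in {ALLOWED_UNITS}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent(self) -> Tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lo, hi) of voxel-center positions, mm."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def same_geometry(self, other: "VoxelGrid | Mask", atol: float = _GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VoxelGrid":
        """New grid sharing this geometry."""
        return VoxelGrid(values, self.spacing, self.origin, unit or self.unit)


@dataclass
class Mask:
    """Boolean voxel mask aligned to a reference geometry."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise GeometryError("mask values must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("mask spacing must be strictly positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_cm3(self) -> float:
        """Structure volume = voxel count x voxel volume."""
        return self.voxel_count * self.voxel_volume_cm3

    def same_geometry(self, other: "VoxelGrid | Mask", atol: float = _GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def centroid_mm(self) -> np.ndarray:
        """World-frame centroid of the set voxels (mm)."""
        idx = np.argwhere(self.values)
        if idx.size == 0:
            return np.full(3, np.nan)
        return np.asarray(self.origin) + idx.mean(axis=0) * np.asarray(self.spacing)

    def __and__(self, other: "Mask") -> "Mask":
        if not self.same_geometry(other):
            raise GeometryError("mask geometries differ")
        return Mask(self.values & other.values, self.spacing, self.origin)

    def __invert__(self) -> "Mask":
        return Mask(~self.values, self.spacing, self.origin)


def normalize_contour(points) -> np.ndarray:
    """Validate one planar contour and close it (first point == last).

    Accepts an (N, 3) array-like of mm coordinates with constant z.  Returns
    a float array whose last row equals the first.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ContourParseError(f"contour must be (N, 3), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ContourParseError("contour contains non-finite coordinates")
    closed = np.allclose(pts[0], pts[-1])
    n_unique = pts.shape[0] - (1 if closed else 0)
    if n_unique < 3:
        raise ContourParseError(f"contour needs >=3 distinct points, got {n_unique}")
    if not np.allclose(pts[:, 2], pts[0, 2], atol=1e-6):
        raise ContourParseError("contour points must share a single z plane")
    if not closed:
        pts = np.vstack([pts, pts[:1]])
    return pts


@dataclass
class StructureSet:
    """Named collections of planar closed contours in patient mm coordinates."""

    structures: Dict[str, List[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.structures = {
            str(name): [normalize_contour(c) for c in contours]
            for name, contours in self.structures.items()
        }

    @property
    def names(self) -> List[str]:
        return list(self.structures)

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __getitem__(self, name: str) -> List[np.ndarray]:
        return self.structures[name]

    def add(self, name: str, contours) -> None:
        self.structures[name] = [normalize_contour(c) for c in contours]


@dataclass
class DensityTable:
    """Piecewise-linear HU -> mass density (g/cm^3) conversion table."""

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.hu.ndim != 1 or self.hu.size < 2 or self.hu.shape != self.density.shape:
            raise DataError("table needs >=2 (hu, density) breakpoints")
        if not np.all(np.diff(self.hu) > 0):
            raise DataError("HU breakpoints must be strictly increasing")
        if np.any(self.density < 0):
            raise DataError("densities must be >= 0")

    def lookup(self, hu_values: np.ndarray) -> np.ndarray:
        """Interpolate densities; clamps to end densities outside the range."""
        return np.interp(np.asarray(hu_values, dtype=float), self.hu, self.density)

    def invert(self, density_values: np.ndarray) -> np.ndarray:
        """Map densities back to HU (requires strictly increasing densities)."""
        if not np.all(np.diff(self.density) > 0):
            raise DataError("inverse lookup needs strictly increasing densities")
        return np.interp(np.asarray(density_values, dtype=float), self.density, self.hu)
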