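"""Cumulative dose-volume / dose-mass histograms and scalar dose metrics.

The histograms are cumulative with the ">= dose" convention: bin ``k`` holds
the amount of structure (volume in cm^3 or mass in g) receiving at least
``bin_edges[k]``.  Scalar metrics (Dmean, Vx, Mx) are computed from the raw
masked voxel values by exact recount, never from the binned curves, so bin
width only affects exported curves.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DataError, DosemassError, EmptyStructureError, GeometryError
from .io_formats.types import Mask, VoxelGrid

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass
class CumulativeHistogram:
    """Cumulative histogram of volume (cm^3) or mass (g) vs dose (Gy)."""

    bin_edges: np.ndarray
    cumulative: np.ndarray
    unit: str  # "cm3" or "g"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.bin_edges.shape != self.cumulative.shape:
            raise DosemassError("bin_edges and cumulative must have equal length")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise DosemassError("cumulative histogram must be non-increasing")

    @property
    def total(self) -> float:
        """Amount at dose 0 (full structure volume or mass)."""
        return float(self.cumulative[0])

    @property
    def relative_pct(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.cumulative)
        return 100.0 * self.cumulative / self.total

    def to_csv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dose_gy", f"cumulative_{self.unit}", "relative_pct"])
            for edge, amount, rel in zip(self.bin_edges, self.cumulative, self.relative_pct):
                writer.writerow([f"{edge:.6g}", repr(float(amount)), f"{rel:.6f}"])


@dataclass
class DoseMetrics:
    """Scalar DVH/DMH metrics for one structure."""

    dmean_volume: float
    dmean_mass: float | None
    volume_cm3: float
    mass_g: float | None
    vx_rel: Dict[float, float] = field(default_factory=dict)
    vx_abs: Dict[float, float] = field(default_factory=dict)
    mx_rel: Dict[float, float] = field(default_factory=dict)
    mx_abs: Dict[float, float] = field(default_factory=dict)

    @property
    def mean_density_g_cm3(self) -> float | None:
        if self.mass_g is None or self.volume_cm3 == 0:
            return None
        return self.mass_g / self.volume_cm3

    def as_dict(self) -> dict:
        out = {
            "dmean_volume_gy": self.dmean_volume,
            "dmean_mass_gy": self.dmean_mass,
            "volume_cm3": self.volume_cm3,
            "mass_g": self.mass_g,
            "mean_density_g_cm3": self.mean_density_g_cm3,
            "vx_rel_pct": {str(k): v for k, v in self.vx_rel.items()},
            "vx_abs_cm3": {str(k): v for k, v in self.vx_abs.items()},
            "mx_rel_pct": {str(k): v for k, v in self.mx_rel.items()},
            "mx_abs_g": {str(k): v for k, v in self.mx_abs.items()},
        }
        return out


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(source: VoxelGrid, target: VoxelGrid | Mask) -> VoxelGrid:
    """Trilinearly resample ``source`` onto the geometry of ``target``.

    Target voxel centers outside the source extent get 0; the number of such
    points is logged and stored on the returned grid as
    ``outside_count`` metadata.

    Raises
    ------
    GeometryError
        If the physical extents are disjoint.
    """
    src_lo, src_hi = _extent(source)
    tgt_lo, tgt_hi = _extent(target)
    if np.any(src_hi < tgt_lo) or np.any(tgt_hi < src_lo):
        raise GeometryError("source and target extents are disjoint")

    nx, ny, nz = target.shape
    axes = [
        (np.asarray(target.origin)[a] + np.asarray(target.spacing)[a] * np.arange(target.shape[a])
         - source.origin[a]) / source.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()])
    outside = np.zeros(coords.shape[1], dtype=bool)
    for a, n in enumerate(source.shape):
        outside |= (coords[a] < 0) | (coords[a] > n - 1)
    values = map_coordinates(
        np.asarray(source.values, dtype=float), coords, order=1, mode="constant", cval=0.0
    )
    values[outside] = 0.0
    outside_count = int(outside.sum())
    if outside_count:
        log.warning("resample_to_grid: %d target voxels outside source extent -> 0", outside_count)
    out = VoxelGrid(values.reshape(nx, ny, nz), target.spacing, target.origin, source.unit)
    out.outside_count = outside_count  # diagnostics, not part of the dataclass
    return out


def _extent(grid) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(grid.origin, dtype=float)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    return lo, hi


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def _check_aligned(dose: VoxelGrid, mask: Mask) -> None:
    if not mask.same_geometry(dose):
        raise GeometryError("dose grid is not aligned to the mask (resample first)")


def _edges(max_dose: float, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise DataError("bin_width must be > 0")
    n = int(np.ceil(max(max_dose, 0.0) / bin_width)) + 2
    return bin_width * np.arange(n)


def compute_dvh(dose: VoxelGrid, mask: Mask, bin_width: float = DEFAULT_BIN_WIDTH_GY) -> CumulativeHistogram:
    """Cumulative dose-volume histogram of the masked region, in cm^3."""
    _check_aligned(dose, mask)
    doses = np.asarray(dose.values, dtype=float)[mask.values]
    if doses.size == 0:
        raise EmptyStructureError("empty mask: DVH undefined")
    edges = _edges(doses.max(), bin_width)
    order = np.sort(doses)
    # voxels with dose >= edge: those beyond the first index where order >= edge
    counts = doses.size - np.searchsorted(order, edges, side="left")
    return CumulativeHistogram(edges, counts * mask.voxel_volume_cm3, unit="cm3")


def compute_dmh(
    dose: VoxelGrid,
    mask: Mask,
    density: VoxelGrid,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> CumulativeHistogram:
    """Cumulative dose-mass histogram of the masked region, in g."""
    _check_aligned(dose, mask)
    if not mask.same_geometry(density):
        raise GeometryError("density grid is not aligned to the mask")
    sel = mask.values
    doses = np.asarray(dose.values, dtype=float)[sel]
    if doses.size == 0:
        raise EmptyStructureError("empty mask: DMH undefined")
    rho = np.asarray(density.values, dtype=float)[sel]
    if np.any(rho < 0):
        raise DataError("negative mass density inside structure")
    masses = rho * mask.voxel_volume_cm3  # g per voxel
    edges = _edges(doses.max(), bin_width)
    order = np.argsort(doses)
    sorted_masses = masses[order]
    # suffix sums: mass of voxels with dose >= edge
    suffix = np.concatenate([np.cumsum(sorted_masses[::-1])[::-1], [0.0]])
    idx = np.searchsorted(doses[order], edges, side="left")
    return CumulativeHistogram(edges, suffix[idx], unit="g")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(
    dose: VoxelGrid,
    mask: Mask,
    density: VoxelGrid | None = None,
    dose_levels: Sequence[float] = (),
) -> DoseMetrics:
    """Exact-recount Dmean / Vx / Mx metrics for one structure.

    ``Vx``/``Mx`` use the ">= x Gy" convention.  ``density`` may be omitted
    for DVH-only structures (e.g. the heart), in which case mass metrics are
    ``None``.
    """
    _check_aligned(dose, mask)
    sel = mask.values
    doses = np.asarray(dose.values, dtype=float)[sel]
    if doses.size == 0:
        raise EmptyStructureError("empty mask: metrics undefined")
    if any(level < 0 for level in dose_levels):
        raise DataError("dose levels must be >= 0")
    vv = mask.voxel_volume_cm3
    volume = doses.size * vv
    out = DoseMetrics(
        dmean_volume=float(doses.mean()),
        dmean_mass=None,
        volume_cm3=volume,
        mass_g=None,
    )
    masses = None
    if density is not None:
        if not mask.same_geometry(density):
            raise GeometryError("density grid is not aligned to the mask")
        rho = np.asarray(density.values, dtype=float)[sel]
        if np.any(rho < 0):
            raise DataError("negative mass density inside structure")
        masses = rho * vv
        total_mass = float(masses.sum())
        if total_mass <= 0:
            raise EmptyStructureError("structure has zero mass: mass metrics undefined")
        out.mass_g = total_mass
        out.dmean_mass = float((masses * doses).sum() / total_mass)
    for level in dose_levels:
        level = float(level)
        hit = doses >= level
        v_abs = float(hit.sum()) * vv
        out.vx_abs[level] = v_abs
        out.vx_rel[level] = 100.0 * v_abs / volume
        if masses is not None:
            m_abs = float(masses[hit].sum())
            out.mx_abs[level] = m_abs
            out.mx_rel[level] = 100.0 * m_abs / out.mass_g
    return out
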