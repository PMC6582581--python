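"""Contour -> voxel mask rasterization.

A voxel is included iff its center lies inside the contour polygon by the
even-odd (crossing-parity) rule.  Contours are assigned to the nearest grid
slice; a contour further than half the slice spacing from any slice is an
error.  Multiple contours on one slice combine by XOR, so disjoint contours
union and nested contours create holes.
"""

from __future__ import annotations

import numpy as np

from ..errors import RasterizationError
from .types import Mask, StructureSet, VoxelGrid

_Z_EPS = 1e-6


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd test of flat point arrays against one closed polygon (N, 2)."""
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[:-1, 0], poly[:-1, 1]
    x2, y2 = poly[1:, 0], poly[1:, 1]
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edges never cross a horizontal ray's y level
        crosses_y = (ey1 > py) != (ey2 > py)
        with np.errstate(invalid="ignore"):
            x_at = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses_y & (px < x_at)
    return inside


def rasterize_contours(contours, reference: VoxelGrid | Mask) -> Mask:
    """Rasterize a list of planar closed contours onto a reference grid."""
    nx, ny, nz = reference.shape
    sx, sy, sz = reference.spacing
    ox, oy, oz = reference.origin
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    px, py = px.ravel(), py.ravel()

    values = np.zeros((nx, ny, nz), dtype=bool)
    for contour in contours:
        contour = np.asarray(contour, dtype=float)
        if not np.allclose(contour[0], contour[-1]):  # close the polygon
            contour = np.vstack([contour, contour[:1]])
        zc = float(contour[0, 2])
        fz = (zc - oz) / sz
        iz = int(round(fz))
        if iz < 0 or iz >= nz or abs(fz - iz) > 0.5 + _Z_EPS:
            raise RasterizationError(
                f"contour at z={zc:.3f} mm matches no slice within half the slice "
                f"spacing ({sz / 2:.3f} mm)"
            )
        inside = _points_in_polygon(px, py, contour[:, :2]).reshape(nx, ny)
        values[:, :, iz] ^= inside
    return Mask(values, reference.spacing, reference.origin)


def rasterize(structures: StructureSet, name: str, reference: VoxelGrid | Mask) -> Mask:
    """Rasterize one named structure from a structure set."""
    return rasterize_contours(structures[name], reference)
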