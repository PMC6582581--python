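"""Deformable registration workflow and lung-expansion metrics.

The workflow mirrors a three-step breath-hold analysis:

1. :func:`split_tissue` separates a CT into lung / non-lung images using the
   structure mask (complement filled with a constant HU).
2. :func:`register_deformable` runs a multi-stage free-form cubic B-spline
   registration minimizing mean squared intensity error, coarse-to-fine in
   both image resolution and control-point spacing.
3. :func:`merge_dvf` blends the lung and non-lung displacement fields across
   the mask boundary, after which structures can be carried between frames
   with :func:`warp_mask`.

Field convention: the fixed image is the free-breathing (FB) frame and the
moving image the breath-hold (DIBH) frame, so ``T(x) = x + u(x)`` maps an FB
position to its DIBH position and positive anterior means indicate
expansion.  Displacement components are mm along (+left, +posterior,
+superior); :func:`expansion_metrics` flips signs to report anterior (-y)
and caudal (-z) motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates

from .errors import EmptyStructureError, GeometryError
from .io_formats.metaimage import read_mha, write_mha
from .io_formats.types import Mask, VoxelGrid

log = logging.getLogger(__name__)

DEFAULT_STAGES = 6
DEFAULT_FINEST_CONTROL_SPACING_MM = 20.0
DEFAULT_FILL_HU = -1000.0


@dataclass
class DeformationField:
    """Dense per-voxel displacement (mm) on a reference geometry.

    ``displacements`` has shape ``(nx, ny, nz, 3)``; components are ordered
    (+left, +posterior, +superior).  The field maps fixed-frame (FB)
    positions to moving-frame (DIBH) positions.
    """

    displacements: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    diagnostics: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise GeometryError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise GeometryError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.displacements.shape[:3]

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)


def write_dvf(path: str, dvf: DeformationField) -> None:
    """Export as a 3-component MetaImage volume (components in mm)."""
    grid = VoxelGrid.__new__(VoxelGrid)  # bypass 3-D check for the 4-D payload
    grid.values = dvf.displacements
    grid.spacing = dvf.spacing
    grid.origin = dvf.origin
    grid.unit = "1"
    write_mha(path, grid)


def read_dvf(path: str) -> DeformationField:
    grid = read_mha(path)
    return DeformationField(grid.values, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# Step 1: tissue split
# ---------------------------------------------------------------------------

def split_tissue(
    ct: VoxelGrid, lung_mask: Mask, fill_hu: float = DEFAULT_FILL_HU
) -> Tuple[VoxelGrid, VoxelGrid]:
    """Split a CT into (lung_image, nonlung_image).

    Each output keeps the CT values on its side of the mask and fills the
    complement with ``fill_hu`` so that cross-tissue gradients do not drive
    the registration across the cut border.
    """
    if not lung_mask.same_geometry(ct):
        raise GeometryError("lung mask not aligned to CT")
    if lung_mask.voxel_count == 0:
        raise EmptyStructureError("empty lung mask")
    lung = np.where(lung_mask.values, ct.values, fill_hu)
    nonlung = np.where(lung_mask.values, fill_hu, ct.values)
    lung_img = ct.with_values(lung)
    nonlung_img = ct.with_values(nonlung)
    lung_img.fill_hu = nonlung_img.fill_hu = float(fill_hu)
    return lung_img, nonlung_img


def intensity_match(
    fixed: VoxelGrid,
    fixed_mask: Mask,
    moving: VoxelGrid,
    moving_mask: Mask,
    fill_value: float = DEFAULT_FILL_HU,
) -> Tuple[float, float]:
    """Linear map (a, b) bringing the moving tissue level to the fixed one.

    Chosen so the fill value is preserved and the mean masked intensity of
    the moving image maps onto the fixed one — compensating e.g. the lung
    density drop between breathing phases before MSE matching.
    """
    mean_f = float(np.asarray(fixed.values)[fixed_mask.values].mean())
    mean_m = float(np.asarray(moving.values)[moving_mask.values].mean())
    if abs(mean_m - fill_value) < 1e-9:
        return 1.0, 0.0
    a = (mean_f - fill_value) / (mean_m - fill_value)
    return a, fill_value * (1.0 - a)


# ---------------------------------------------------------------------------
# Step 2: B-spline registration
# ---------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2."""
    t = np.abs(t)
    out = np.zeros_like(t)
    near = t < 1
    mid = (t >= 1) & (t < 2)
    out[near] = (4.0 - 6.0 * t[near] ** 2 + 3.0 * t[near] ** 3) / 6.0
    out[mid] = (2.0 - t[mid]) ** 3 / 6.0
    return out


def _basis_matrix(coords_mm: np.ndarray, control_spacing: float) -> Tuple[np.ndarray, int]:
    """Dense (n_points, n_control) cubic B-spline basis along one axis.

    Control points sit at ``(i - 1) * control_spacing`` relative to the first
    voxel so that the full extent has complete spline support.
    """
    rel = (coords_mm - coords_mm[0]) / control_spacing
    n_ctrl = int(np.floor(rel[-1])) + 4 if coords_mm.size > 1 else 4
    idx = np.arange(n_ctrl) - 1.0
    return _bspline3(rel[:, None] - idx[None, :]), n_ctrl


def _dense_from_coeffs(bx: np.ndarray, by: np.ndarray, bz: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Evaluate the separable spline: (ncx,ncy,ncz,3) -> (nx,ny,nz,3)."""
    t = np.tensordot(bx, c, axes=(1, 0))
    t = np.tensordot(by, t, axes=(1, 1)).transpose(1, 0, 2, 3)
    t = np.tensordot(bz, t, axes=(1, 2)).transpose(1, 2, 0, 3)
    return t


def _coeff_grad_from_dense(bx: np.ndarray, by: np.ndarray, bz: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`_dense_from_coeffs`."""
    t = np.tensordot(bx.T, g, axes=(1, 0))
    t = np.tensordot(by.T, t, axes=(1, 1)).transpose(1, 0, 2, 3)
    t = np.tensordot(bz.T, t, axes=(1, 2)).transpose(1, 2, 0, 3)
    return t


def _affine_prestage(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing: np.ndarray,
    max_iterations: int = 150,
) -> np.ndarray:
    """Global 12-dof affine MSE pre-registration at low resolution.

    Returns the dense displacement field (mm) on the ``fixed`` grid; used to
    initialize the B-spline stages so that large bulk motions (organ
    translation + inflation) are inside their capture range.
    """
    ds = max(1, int(round(min(fixed.shape) / 24)))
    fx = _stage_view(fixed, ds)
    mv = _stage_view(moving, ds)
    st_spacing = spacing * ds
    shape = fx.shape
    axes_mm = [st_spacing[a] * np.arange(shape[a]) for a in range(3)]
    center = np.array([ax[-1] / 2.0 for ax in axes_mm])
    rel = [axes_mm[a] - center[a] for a in range(3)]
    grad_mv = np.gradient(mv, *st_spacing)
    base_idx = [np.arange(shape[a])[(slice(None),) + (None,) * (2 - a)] for a in range(3)]
    n_vox = fx.size

    def unpack(p):
        return p[:9].reshape(3, 3), p[9:]

    def objective(p):
        m, t = unpack(p)
        u = np.empty(shape + (3,))
        for i in range(3):
            u[..., i] = (
                m[i, 0] * rel[0][:, None, None]
                + m[i, 1] * rel[1][None, :, None]
                + m[i, 2] * rel[2][None, None, :]
                + t[i]
            )
        coords = [base_idx[a] + u[..., a] / st_spacing[a] for a in range(3)]
        warped = map_coordinates(mv, coords, order=1, mode="nearest")
        resid = warped - fx
        loss = float(np.mean(resid**2))
        grad = np.zeros(12)
        for i in range(3):
            gi = map_coordinates(grad_mv[i], coords, order=1, mode="nearest")
            dl = (2.0 / n_vox) * resid * gi
            grad[3 * i + 0] = float((dl * rel[0][:, None, None]).sum())
            grad[3 * i + 1] = float((dl * rel[1][None, :, None]).sum())
            grad[3 * i + 2] = float((dl * rel[2][None, None, :]).sum())
            grad[9 + i] = float(dl.sum())
        return loss, grad

    result = optimize.minimize(
        objective,
        np.zeros(12),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "ftol": 1e-12},
    )
    m, t = unpack(result.x)
    full_axes = [spacing[a] * np.arange(fixed.shape[a]) - center[a] for a in range(3)]
    u = np.empty(fixed.shape + (3,))
    for i in range(3):
        u[..., i] = (
            m[i, 0] * full_axes[0][:, None, None]
            + m[i, 1] * full_axes[1][None, :, None]
            + m[i, 2] * full_axes[2][None, None, :]
            + t[i]
        )
    return u


def default_schedule(
    stages: int = DEFAULT_STAGES,
    finest_control_spacing_mm: float = DEFAULT_FINEST_CONTROL_SPACING_MM,
) -> List[Tuple[int, float]]:
    """Coarse-to-fine list of (image_downsample_factor, control_spacing_mm)."""
    if stages < 1:
        raise GeometryError("stages must be >= 1")
    schedule = []
    for i in range(stages):
        frac = i / (stages - 1) if stages > 1 else 1.0
        ds = int(round(4.0 ** (1.0 - frac)))
        cs = finest_control_spacing_mm * 4.0 ** (1.0 - frac)
        schedule.append((max(ds, 1), cs))
    return schedule


def _stage_view(values: np.ndarray, ds: int) -> np.ndarray:
    if ds == 1:
        return np.asarray(values, dtype=float)
    smoothed = gaussian_filter(np.asarray(values, dtype=float), sigma=0.5 * ds)
    return smoothed[::ds, ::ds, ::ds]


def _mse(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray, spacing) -> float:
    coords = [
        np.arange(fixed.shape[a])[
            (slice(None),) + (None,) * (2 - a)
        ] + u[..., a] / spacing[a]
        for a in range(3)
    ]
    warped = map_coordinates(moving, coords, order=1, mode="nearest")
    return float(np.mean((warped - fixed) ** 2))


def register_deformable(
    fixed: VoxelGrid,
    moving: VoxelGrid,
    stages: int = DEFAULT_STAGES,
    grid_schedule: Sequence[Tuple[int, float]] | None = None,
    max_iterations: int = 60,
    smooth_weight: float = 3e-2,
    moving_rescale: Tuple[float, float] | None = None,
    affine_init: bool = True,
    verbose: bool = False,
) -> DeformationField:
    """Multi-stage free-form cubic B-spline registration (MSE metric).

    Returns the dense displacement field on the fixed geometry.  The final
    MSE never exceeds the identity-transform MSE: if the optimization fails
    to improve on identity the zero field is returned (recorded in
    diagnostics, not raised).

    ``moving_rescale = (a, b)`` applies ``a * moving + b`` before matching.
    An MSE metric cannot reconcile a systematic intensity offset between
    corresponding tissues (e.g. the lung density drop between breathing
    phases), so callers registering cross-phase lung images should rescale
    the moving image to the fixed image's tissue level first.
    """
    if not fixed.same_geometry(moving):
        from .dosimetry import resample_to_grid  # local import avoids a cycle

        moving = resample_to_grid(moving, fixed)
    schedule = list(grid_schedule) if grid_schedule is not None else default_schedule(stages)
    if len(schedule) < 1:
        raise GeometryError("empty registration schedule")

    fixed_full = np.asarray(fixed.values, dtype=float)
    moving_full = np.asarray(moving.values, dtype=float)
    if moving_rescale is not None:
        moving_full = moving_rescale[0] * moving_full + moving_rescale[1]
    # normalize intensities for optimization; contract MSE uses raw values
    scale = np.std(np.concatenate([fixed_full.ravel(), moving_full.ravel()]))
    scale = scale if scale > 0 else 1.0
    spacing = np.asarray(fixed.spacing)
    full_axes_mm = [fixed.spacing[a] * np.arange(fixed.shape[a]) for a in range(3)]

    u_full = np.zeros(fixed.shape + (3,))
    diagnostics: list = []
    if affine_init:
        u_full = _affine_prestage(fixed_full / scale, moving_full / scale, spacing)
        diagnostics.append(
            {"stage": "affine", "mse_after": _mse(fixed_full, moving_full, u_full, spacing)}
        )
    for stage_idx, (ds, cs) in enumerate(schedule):
        ds = int(max(1, ds))
        fx = _stage_view(fixed_full, ds) / scale
        mv = _stage_view(moving_full, ds) / scale
        st_spacing = spacing * ds
        st_shape = fx.shape
        if min(st_shape) < 4:
            diagnostics.append({"stage": stage_idx, "skipped": "image too small at this level"})
            continue
        axes_mm = [st_spacing[a] * np.arange(st_shape[a]) for a in range(3)]
        cs_eff = min(cs, max(float(axes_mm[a][-1]) for a in range(3)) / 2.0)
        cs_eff = max(cs_eff, float(max(st_spacing)))
        basis = [_basis_matrix(axes_mm[a], cs_eff) for a in range(3)]
        bx, by, bz = (b[0] for b in basis)
        nc = tuple(b[1] for b in basis)

        u_base = u_full[::ds, ::ds, ::ds] if ds > 1 else u_full
        base_idx = [
            np.arange(st_shape[a])[(slice(None),) + (None,) * (2 - a)] for a in range(3)
        ]
        grad_mv = np.gradient(mv, *st_spacing)  # d(intensity)/d(mm)
        n_vox = fx.size

        def objective(cflat):
            c = cflat.reshape(nc + (3,))
            u = _dense_from_coeffs(bx, by, bz, c) + u_base
            coords = [base_idx[a] + u[..., a] / st_spacing[a] for a in range(3)]
            warped = map_coordinates(mv, coords, order=1, mode="nearest")
            resid = warped - fx
            loss = float(np.mean(resid**2))
            dl_du = np.empty(st_shape + (3,))
            for a in range(3):
                ga = map_coordinates(grad_mv[a], coords, order=1, mode="nearest")
                dl_du[..., a] = (2.0 / n_vox) * resid * ga
            grad_c = _coeff_grad_from_dense(bx, by, bz, dl_du)
            # smoothness: mean squared strain of the control lattice
            # (coefficient differences / control spacing -> dimensionless)
            reg = 0.0
            if smooth_weight > 0:
                w = smooth_weight / (c.size * cs_eff**2)
                for a in range(3):
                    d = np.diff(c, axis=a)
                    reg += w * float(np.sum(d**2))
                    grad_d = np.zeros_like(c)
                    sl_lo = [slice(None)] * 4
                    sl_hi = [slice(None)] * 4
                    sl_lo[a] = slice(0, -1)
                    sl_hi[a] = slice(1, None)
                    grad_d[tuple(sl_lo)] -= 2.0 * d
                    grad_d[tuple(sl_hi)] += 2.0 * d
                    grad_c += w * grad_d
            return loss + reg, grad_c.ravel()

        c0 = np.zeros(int(np.prod(nc)) * 3)
        mse_before = _mse(fx, mv, u_base, st_spacing)
        result = optimize.minimize(
            objective,
            c0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": 1e-10, "gtol": 1e-8},
        )
        c_opt = result.x.reshape(nc + (3,))
        # evaluate the stage spline on the full-resolution grid (exact, no zoom)
        full_basis = [
            _bspline3(
                (full_axes_mm[a] / cs_eff)[:, None] - (np.arange(nc[a]) - 1.0)[None, :]
            )
            for a in range(3)
        ]
        u_full = u_full + _dense_from_coeffs(*full_basis, c_opt)
        mse_after = _mse(fx, mv, u_full[::ds, ::ds, ::ds] if ds > 1 else u_full, st_spacing)
        diagnostics.append(
            {
                "stage": stage_idx,
                "downsample": ds,
                "control_spacing_mm": cs_eff,
                "mse_before": mse_before * scale**2,
                "mse_after": mse_after * scale**2,
                "iterations": int(result.nit),
            }
        )
        if verbose:
            log.info(
                "stage %d (ds=%d, cs=%.1f mm): MSE %.4g -> %.4g (%d iter)",
                stage_idx, ds, cs_eff, mse_before, mse_after, result.nit,
            )

    identity_mse = float(np.mean((moving_full - fixed_full) ** 2))
    final_mse = _mse(fixed_full, moving_full, u_full, spacing)
    if final_mse > identity_mse:
        diagnostics.append({"fallback": "identity", "final_mse": final_mse, "identity_mse": identity_mse})
        u_full = np.zeros(fixed.shape + (3,))
        final_mse = identity_mse
    diagnostics.append({"identity_mse": identity_mse, "final_mse": final_mse})
    return DeformationField(u_full, fixed.spacing, fixed.origin, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Step 3: merge + structure warping
# ---------------------------------------------------------------------------

def merge_dvf(
    lung_dvf: DeformationField,
    nonlung_dvf: DeformationField,
    lung_mask: Mask,
    band_voxels: int = 3,
) -> DeformationField:
    """Blend the lung field (inside the mask) with the non-lung field.

    ``band_voxels = 0`` gives the exact piecewise field; otherwise a linear
    cross-fade over roughly ``band_voxels`` voxels around the boundary, with
    weight 0.5 at the interface (so symmetric voxels average the two fields).
    """
    if not lung_dvf.same_geometry(nonlung_dvf):
        raise GeometryError("lung and non-lung fields have different geometry")
    if lung_mask.shape != lung_dvf.shape:
        raise GeometryError("mask geometry does not match the fields")
    m = lung_mask.values
    if band_voxels <= 0:
        w = m.astype(float)
    else:
        signed = distance_transform_edt(m) - distance_transform_edt(~m)
        w = np.clip(0.5 + signed / (band_voxels + 1.0), 0.0, 1.0)
    merged = w[..., None] * lung_dvf.displacements + (1.0 - w[..., None]) * nonlung_dvf.displacements
    return DeformationField(merged, lung_dvf.spacing, lung_dvf.origin)


def warp_mask(mask: Mask, dvf: DeformationField) -> Mask:
    """Pull a moving-frame mask back into the fixed frame.

    ``warped(x) = mask(x + u(x))`` with nearest-neighbor sampling, so a mask
    defined in the moving (DIBH) frame lands on the fixed (FB) grid.  A mask
    translated by ``+t`` relative to the fixed frame therefore comes back to
    its fixed-frame position when warped through the constant field ``+t``.
    """
    if mask.shape != dvf.shape or not np.allclose(mask.spacing, dvf.spacing):
        raise GeometryError("mask and field geometry differ")
    coords = [
        np.arange(mask.shape[a])[(slice(None),) + (None,) * (2 - a)]
        + dvf.displacements[..., a] / mask.spacing[a]
        for a in range(3)
    ]
    warped = map_coordinates(mask.values.astype(np.uint8), coords, order=0, mode="constant", cval=0)
    out = Mask(warped.astype(bool), mask.spacing, mask.origin)
    if mask.voxel_count:
        change = 100.0 * (out.voxel_count - mask.voxel_count) / mask.voxel_count
        log.info("warp_mask: volume change %.2f%%", change)
    return out


# ---------------------------------------------------------------------------
# Expansion metrics
# ---------------------------------------------------------------------------

@dataclass
class ExpansionMetrics:
    """Mean directional expansion (mm) of a structure and derived indices.

    ``expansion_3d`` is the Euclidean norm of the mean displacement vector
    (per-structure); ``expansion_3d_mean_of_norms`` averages per-voxel
    displacement magnitudes instead.  ``breathing_index`` is
    ``(caudal - anterior) / anterior * 100`` (%): negative = chest-dominant
    (anterior) breathing, positive = abdominal-dominant.
    """

    mean_left: float
    mean_anterior: float
    mean_caudal: float
    expansion_3d: float
    expansion_3d_mean_of_norms: float
    breathing_index: float
    breathing_index_defined: bool

    def as_dict(self) -> dict:
        return {
            "mean_left_mm": self.mean_left,
            "mean_anterior_mm": self.mean_anterior,
            "mean_caudal_mm": self.mean_caudal,
            "expansion_3d_mm": self.expansion_3d,
            "expansion_3d_mean_of_norms_mm": self.expansion_3d_mean_of_norms,
            "breathing_index_pct": self.breathing_index,
            "breathing_index_defined": self.breathing_index_defined,
        }


def expansion_metrics(dvf: DeformationField, mask: Mask) -> ExpansionMetrics:
    """Mean displacement of a structure along left / anterior / caudal.

    Signs: the field stores (+left, +posterior, +superior) components;
    anterior = -posterior and caudal = -superior.
    """
    if mask.shape != dvf.shape:
        raise GeometryError("mask and field geometry differ")
    if mask.voxel_count == 0:
        raise EmptyStructureError("empty mask: expansion undefined")
    d = dvf.displacements[mask.values]  # (n, 3)
    mean_vec = d.mean(axis=0)
    mean_left = float(mean_vec[0])
    mean_anterior = float(-mean_vec[1])
    mean_caudal = float(-mean_vec[2])
    expansion_3d = float(np.sqrt(mean_left**2 + mean_anterior**2 + mean_caudal**2))
    mean_of_norms = float(np.linalg.norm(d, axis=1).mean())
    if mean_anterior == 0.0:
        index, defined = float("nan"), False
    else:
        index, defined = (mean_caudal - mean_anterior) * 100.0 / mean_anterior, True
    return ExpansionMetrics(
        mean_left=mean_left,
        mean_anterior=mean_anterior,
        mean_caudal=mean_caudal,
        expansion_3d=expansion_3d,
        expansion_3d_mean_of_norms=mean_of_norms,
        breathing_index=index,
        breathing_index_defined=defined,
    )
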