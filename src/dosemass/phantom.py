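"""Synthetic paired FB/DIBH thorax phantoms with known ground truth.

Each pair consists of CT (HU), contoured structures and a tangential-beam
dose grid for both breathing phases, plus the analytic deformation field
that maps free-breathing (FB) lung positions to breath-hold (DIBH)
positions.

Construction principles
-----------------------
* The left lung is an ellipsoid; the DIBH lung is the FB lung scaled
  isotropically about its center by ``expansion_factor ** (1/3)`` and
  translated by the requested mean expansions, so the mean ground-truth
  displacement over the lung equals the requested vector exactly.
* Lung mass is conserved: the DIBH lung density field is rescaled so the
  rasterized DIBH lung mass equals the FB lung mass before HU noise.
* The two-tangent field is modeled as a half-space anchored to the
  anterior-left lung surface of each phase at a constant penetration depth,
  band-limited in z, with a Gaussian penumbra and exponential scatter tail;
  dose is renormalized to the prescription at the median PTV voxel.  The
  per-phase anchoring emulates plans conformed to the chest wall, which is
  what makes the relative irradiated lung volume drop while the absolute
  volume rises under expansion.
* "Adverse anatomy" pairs carry a dense patch inside the in-field DIBH lung
  (lung tissue replacing previously irradiated heart/abdomen tissue), which
  raises the irradiated lung mass in DIBH while total mass stays conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely.geometry import Polygon

from .errors import ParameterError
from .io_formats.density import default_density_table
from .io_formats.raster import rasterize
from .io_formats.types import Mask, StructureSet, VoxelGrid
from .registration import DeformationField

SOFT_TISSUE_DENSITY = 1.00
HEART_DENSITY = 1.05
AIR_DENSITY = 0.00121


@dataclass
class PhantomParams:
    """Geometry, tissue and beam parameters of one synthetic patient."""

    shape: Tuple[int, int, int] = (96, 96, 112)
    spacing: Tuple[float, float, float] = (2.5, 2.5, 3.0)
    body_half_axes: Tuple[float, float] = (112.0, 95.0)
    lung_volume_cm3: float = 1432.0
    lung_aspect_z: float = 1.8  # superior-inferior half-axis / lateral half-axis
    lung_center: Tuple[float, float, float] = (40.0, 8.0, 6.0)
    lung_density: float = 0.31
    expansion_factor: float = 1.8
    expansion_left_mm: float = 1.5
    expansion_anterior_mm: float = 16.0
    expansion_caudal_mm: float = 12.2
    density_texture: float = 0.25  # relative amplitude of smooth lung texture
    heart_center: Tuple[float, float, float] = (10.0, -20.0, -70.0)
    heart_radius_mm: float = 42.0
    # extra heart displacement on top of the lung's affine map (the carve
    # follows the affine map exactly so the ground-truth field stays
    # consistent with the geometry; this adds a rigid perturbation)
    heart_displacement: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_angle_deg: float = 30.0
    field_depth_mm: float = 34.0  # penetration beyond the anterior-left lung surface
    field_half_z_mm: float = 60.0
    field_center_z_mm: float = 0.0
    penumbra_sigma_mm: float = 5.0
    scatter_fraction: float = 0.08
    scatter_length_mm: float = 25.0
    prescription_gy: float = 50.0
    ptv_depth_mm: float = 30.0  # chest-wall PTV thickness inward of the body surface
    ptv_half_z_mm: float = 55.0
    noise_hu: float = 8.0
    psf_sigma_mm: float = 1.5  # scanner point-spread blur applied to density
    adverse: bool = False
    adverse_patch_radius_mm: float = 32.0
    adverse_patch_density: float = 0.85
    seed: int = 0
    # internal: correction applied so the carved (lung minus heart) DIBH/FB
    # volume ratio matches expansion_factor despite the heart carve
    scale_adjust: float = 1.0
    # internal: translation correction so the mean ground-truth displacement
    # over the carved lung equals the requested expansions exactly
    shift_adjust: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.expansion_factor <= 1.0:
            raise ParameterError("expansion_factor must be > 1")
        if not (0.0 < self.lung_density < 2.0):
            raise ParameterError("lung_density must lie in (0, 2)")
        for name in ("lung_volume_cm3", "heart_radius_mm", "prescription_gy", "field_depth_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def field_normal(self) -> np.ndarray:
        a = math.radians(self.field_angle_deg)
        return np.array([math.sin(a), -math.cos(a), 0.0])  # anterior-left

    @property
    def lung_half_axes(self) -> np.ndarray:
        a = (3.0 * self.lung_volume_cm3 * 1000.0 / (4.0 * math.pi * self.lung_aspect_z)) ** (1.0 / 3.0)
        return np.array([a, a, self.lung_aspect_z * a])

    @property
    def scale(self) -> float:
        return self.expansion_factor ** (1.0 / 3.0) * self.scale_adjust

    @property
    def lung_shift(self) -> np.ndarray:
        # (+left, +posterior, +superior) components of the mean lung expansion
        return np.array(
            [self.expansion_left_mm, -self.expansion_anterior_mm, -self.expansion_caudal_mm]
        ) + np.asarray(self.shift_adjust)


@dataclass
class PhantomPhase:
    ct: VoxelGrid
    structures: StructureSet
    dose: Optional[VoxelGrid]  # None when generated with with_dose=False
    density: VoxelGrid  # construction density before HU noise (ground truth)


@dataclass
class PatientPair:
    fb: PhantomPhase
    dibh: PhantomPhase
    ground_truth_dvf: DeformationField
    params: PhantomParams

    def mask(self, phase: str, name: str) -> Mask:
        ph = self.fb if phase == "fb" else self.dibh
        return rasterize(ph.structures, name, ph.ct)


# ---------------------------------------------------------------------------
# Contour construction
# ---------------------------------------------------------------------------

def _ring(cx: float, cy: float, ax: float, ay: float, n: int = 96) -> Polygon:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + ax * np.cos(t), cy + ay * np.sin(t)]))


def _polygon_contours(geom, z: float) -> List[np.ndarray]:
    polys = [geom] if isinstance(geom, Polygon) else list(getattr(geom, "geoms", []))
    contours = []
    for poly in polys:
        if poly.is_empty or poly.area < 4.0:
            continue
        for ring in [poly.exterior, *poly.interiors]:  # holes XOR out at raster time
            xy = np.asarray(ring.coords)
            if len(xy) >= 4:
                contours.append(np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), z)]))
    return contours


def _ellipsoid_slice(center, half_axes, z: float) -> Optional[Polygon]:
    rel = (z - center[2]) / half_axes[2]
    if abs(rel) >= 0.999:
        return None
    r = math.sqrt(1.0 - rel * rel)
    if r * min(half_axes[0], half_axes[1]) < 2.0:
        return None
    return _ring(center[0], center[1], half_axes[0] * r, half_axes[1] * r)


def _halfplane(normal: np.ndarray, offset: float, reach: float = 500.0) -> Polygon:
    """Polygon approximating {p : n . p >= offset} within +-reach mm."""
    n2 = np.asarray(normal[:2], dtype=float)
    n2 = n2 / np.linalg.norm(n2)
    t = np.array([-n2[1], n2[0]])
    base = n2 * offset
    pts = [
        base + reach * t,
        base - reach * t,
        base - reach * t + reach * n2,
        base + reach * t + reach * n2,
    ]
    return Polygon(pts)


def _build_structures(params: PhantomParams, phase: str, grid: VoxelGrid) -> StructureSet:
    p = params
    zs = grid.axis_coords(2)
    if phase == "fb":
        lung_c = np.asarray(p.lung_center, dtype=float)
        lung_ax = p.lung_half_axes
        heart_c = np.asarray(p.heart_center, dtype=float)
        heart_r = p.heart_radius_mm
    else:
        lung_c = np.asarray(p.lung_center, dtype=float) + p.lung_shift
        lung_ax = p.lung_half_axes * p.scale
        heart_c = _dibh_heart_center(p)
        heart_r = p.scale * p.heart_radius_mm
    structures: Dict[str, list] = {"body": [], "left_lung": [], "heart": [], "ptv": []}
    body_poly = _ring(0.0, 0.0, p.body_half_axes[0], p.body_half_axes[1], n=128)
    # PTV is chest wall anchored to the (static) body surface, so it is the
    # same in both phases; the per-phase field always covers it
    n = p.field_normal
    body_support = math.sqrt((p.body_half_axes[0] * n[0]) ** 2 + (p.body_half_axes[1] * n[1]) ** 2)
    ptv_poly = body_poly.intersection(_halfplane(n, body_support - p.ptv_depth_mm))
    for z in zs:
        structures["body"].extend(_polygon_contours(body_poly, z))
        lung_poly = _ellipsoid_slice(lung_c, lung_ax, z)
        heart_poly = _ellipsoid_slice(heart_c, np.full(3, heart_r), z)
        if heart_poly is not None:
            structures["heart"].extend(_polygon_contours(heart_poly, z))
        if lung_poly is not None:
            if heart_poly is not None:
                lung_poly = lung_poly.difference(heart_poly)
            structures["left_lung"].extend(_polygon_contours(lung_poly, z))
        if abs(z - p.field_center_z_mm) <= p.ptv_half_z_mm:
            structures["ptv"].extend(_polygon_contours(ptv_poly, z))
    structures = {k: v for k, v in structures.items() if v}
    for required in ("body", "left_lung", "heart", "ptv"):
        if required not in structures:
            raise ParameterError(f"phantom construction produced no {required} contours")
    _check_extents(structures, grid)
    return StructureSet(structures=structures)


def _check_extents(structures: Dict[str, list], grid: VoxelGrid) -> None:
    lo, hi = grid.extent()
    for name, contours in structures.items():
        for c in contours:
            pts = np.asarray(c)
            if np.any(pts[:, :3].min(axis=0) < lo - 1e-6) or np.any(pts[:, :3].max(axis=0) > hi + 1e-6):
                raise ParameterError(f"structure {name!r} exceeds the grid extent")


def _dibh_heart_center(params: PhantomParams) -> np.ndarray:
    """Heart center in DIBH: carried by the lung's affine map plus the
    configured rigid extra displacement."""
    p = params
    c_h = np.asarray(p.heart_center, dtype=float)
    c_l = np.asarray(p.lung_center, dtype=float)
    affine = (p.scale - 1.0) * (c_h - c_l) + p.lung_shift
    return c_h + affine + np.asarray(p.heart_displacement, dtype=float)


def _auto_place(params: PhantomParams) -> PhantomParams:
    """Clamp the lung center so both phases fit inside body and grid."""
    p = params
    ax = p.lung_half_axes * p.scale
    shift = p.lung_shift
    grid_half = (np.asarray(p.shape) - 1) * np.asarray(p.spacing) / 2.0
    margin = 3.0
    c = np.asarray(p.lung_center, dtype=float)
    limits_xy = np.array([p.body_half_axes[0], p.body_half_axes[1], grid_half[2]]) - margin
    for a in range(3):
        hi = limits_xy[a] - ax[a] - max(shift[a], 0.0)
        lo = -limits_xy[a] + ax[a] - min(shift[a], 0.0)
        if lo > hi:
            raise ParameterError("lung cannot fit inside the body/grid with these parameters")
        c[a] = float(np.clip(c[a], lo, hi))
    if not np.allclose(c, p.lung_center):
        p = replace(p, lung_center=tuple(c))
    return p


# ---------------------------------------------------------------------------
# Voxel fields
# ---------------------------------------------------------------------------

def _coords(grid: VoxelGrid) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(
        grid.axis_coords(0), grid.axis_coords(1), grid.axis_coords(2), indexing="ij"
    )


def _make_grid(params: PhantomParams) -> VoxelGrid:
    shape = tuple(int(v) for v in params.shape)
    spacing = params.spacing
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return VoxelGrid(np.zeros(shape), spacing, origin, unit="1")


class _LungTexture:
    """Smooth multiplicative texture field in FB lung mm coordinates.

    A dense Gaussian random field (filtered lattice noise, ~10 mm correlation
    length) standing in for vascular/bronchial structure: it carries
    correspondence information everywhere, which the deformable registration
    needs.  DIBH evaluation goes through the inverse affine map so the
    pattern deforms consistently with the ground-truth transform.  The
    multiplier is clamped to keep densities physical.
    """

    LATTICE_MM = 5.0
    SMOOTH_LATTICE = 2.0  # sigma in lattice units -> ~10 mm correlation

    def __init__(self, rng: np.random.Generator, amplitude: float, half_axes_mm: np.ndarray):
        self.amp = amplitude
        self.extent = 1.4 * np.asarray(half_axes_mm, dtype=float)
        shape = tuple(int(np.ceil(2 * e / self.LATTICE_MM)) + 3 for e in self.extent)
        noise = rng.standard_normal(shape)
        field = gaussian_filter(noise, sigma=self.SMOOTH_LATTICE)
        field -= field.mean()
        self.field = field / field.std()

    def __call__(self, r_mm: np.ndarray) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        idx = (r_mm + self.extent) / self.LATTICE_MM
        flat = idx.reshape(-1, 3).T
        values = map_coordinates(self.field, flat, order=1, mode="nearest")
        return np.clip(1.0 + self.amp * values.reshape(r_mm.shape[:-1]), 0.4, 1.6)


def _density_volume(
    params: PhantomParams,
    grid: VoxelGrid,
    masks: Dict[str, Mask],
    phase: str,
    texture: _LungTexture,
    target_lung_mass_g: float | None,
) -> Tuple[VoxelGrid, float]:
    """Construction density; returns (grid, rasterized lung mass in g)."""
    p = params
    x, y, z = _coords(grid)
    pos = np.stack([x, y, z], axis=-1)
    rho = np.full(grid.shape, AIR_DENSITY)
    rho[masks["body"].values] = SOFT_TISSUE_DENSITY

    c_fb = np.asarray(p.lung_center, dtype=float)
    if phase == "fb":
        q = pos - c_fb
        base = p.lung_density
    else:
        c_dibh = c_fb + p.lung_shift
        # inverse of the affine ground-truth map: back to FB lung mm coords
        q = (pos - c_dibh) / p.scale
        base = p.lung_density / p.expansion_factor
    lung = masks["left_lung"].values
    rho[lung] = base * texture(q[lung])

    if phase == "dibh" and p.adverse:
        patch_center = _adverse_patch_center(p)
        in_patch = lung & (
            np.sum((pos - patch_center) ** 2, axis=-1) <= p.adverse_patch_radius_mm**2
        )
        if target_lung_mass_g is not None and np.any(in_patch):
            vv = grid.voxel_volume_cm3
            patch_mass = p.adverse_patch_density * in_patch.sum() * vv
            rest = lung & ~in_patch
            rest_mass = float(rho[rest].sum()) * vv
            if rest_mass > 0:
                rho[rest] *= max(target_lung_mass_g - patch_mass, 0.1 * rest_mass) / rest_mass
            rho[in_patch] = p.adverse_patch_density

    rho[masks["heart"].values] = HEART_DENSITY
    if p.psf_sigma_mm > 0:  # scanner PSF: makes edges band-limited
        rho = gaussian_filter(rho, sigma=[p.psf_sigma_mm / s for s in grid.spacing])
    if phase == "dibh" and target_lung_mass_g is not None:
        current = float(rho[lung].sum()) * grid.voxel_volume_cm3
        if current > 0:
            rho[lung] *= target_lung_mass_g / current
    lung_mass = float(rho[lung].sum()) * grid.voxel_volume_cm3
    return grid.with_values(rho, unit="g/cm3"), lung_mass


def _adverse_patch_center(params: PhantomParams) -> np.ndarray:
    p = params
    c_dibh = np.asarray(p.lung_center, dtype=float) + p.lung_shift
    ax = p.lung_half_axes * p.scale
    n = p.field_normal
    support = math.sqrt((ax[0] * n[0]) ** 2 + (ax[1] * n[1]) ** 2)
    # ~20 mm beyond the field plane, low in the field z band near the heart
    along = support - p.field_depth_mm + 20.0
    center = c_dibh + n * along
    center[2] = max(p.field_center_z_mm - 30.0, c_dibh[2] - ax[2] * 0.6)
    return center


def generate_tangential_dose(
    ct: VoxelGrid, structures: StructureSet, params: PhantomParams
) -> VoxelGrid:
    """Geometric two-tangent dose model normalized to the PTV median.

    The in-field region is the half-space beyond the anterior-left lung
    support (at ``field_depth_mm`` penetration), limited to the field z band
    and the body; a Gaussian penumbra and an exponential scatter tail are
    applied, and the result is scaled so the median PTV dose equals the
    prescription.  Dose is zero outside the body.
    """
    p = params
    n = p.field_normal
    lung_pts = np.vstack(structures["left_lung"])
    in_band = np.abs(lung_pts[:, 2] - p.field_center_z_mm) <= p.field_half_z_mm
    pts = lung_pts[in_band] if np.any(in_band) else lung_pts
    offset = float(np.max(pts[:, 0] * n[0] + pts[:, 1] * n[1])) - p.field_depth_mm

    body = rasterize(structures, "body", ct).values
    ptv = rasterize(structures, "ptv", ct).values
    x, y, z = _coords(ct)
    infield = (
        (x * n[0] + y * n[1] >= offset)
        & (np.abs(z - p.field_center_z_mm) <= p.field_half_z_mm)
        & body
    )
    sigma_vox = [p.penumbra_sigma_mm / s for s in ct.spacing]
    penumbra = gaussian_filter(infield.astype(float), sigma=sigma_vox)
    dist_mm = distance_transform_edt(~infield, sampling=ct.spacing)
    scatter = p.scatter_fraction * np.exp(-dist_mm / p.scatter_length_mm)
    dose = np.maximum(penumbra, scatter)
    dose[~body] = 0.0

    ptv_doses = dose[ptv]
    if ptv_doses.size == 0:
        raise ParameterError("PTV rasterizes to zero voxels")
    med = float(np.median(ptv_doses))
    if med < 0.25:
        import logging

        logging.getLogger(__name__).warning(
            "PTV largely outside the field (median raw dose %.3f); normalizing anyway", med
        )
    return ct.with_values(dose * (p.prescription_gy / med), unit="Gy")


def _ground_truth_dvf(params: PhantomParams, grid: VoxelGrid) -> DeformationField:
    """Analytic FB->DIBH field.

    Affine (scaling + translation) inside the lung with a smooth decay
    outside, blended toward the rigid heart displacement near the heart so
    the carved lung-heart interface moves consistently with the heart.
    """
    p = params
    x, y, z = _coords(grid)
    pos = np.stack([x, y, z], axis=-1)
    c = np.asarray(p.lung_center, dtype=float)
    rel = (pos - c) / p.lung_half_axes
    r = np.sqrt(np.sum(rel**2, axis=-1))
    w_lung = np.exp(-np.clip(r - 1.0, 0.0, None) ** 2 / (2.0 * 0.25**2))
    affine = (p.scale - 1.0) * (pos - c) + p.lung_shift
    u = w_lung[..., None] * affine

    extra = np.asarray(p.heart_displacement, dtype=float)
    if np.any(extra != 0.0):
        heart_c = np.asarray(p.heart_center, dtype=float)
        rh = np.sqrt(np.sum((pos - heart_c) ** 2, axis=-1)) / p.heart_radius_mm
        w_heart = np.exp(-np.clip(rh - 1.0, 0.0, None) ** 2 / (2.0 * 0.15**2))
        u = u + w_heart[..., None] * extra
    return DeformationField(u, grid.spacing, grid.origin)


def generate_pair(
    params: PhantomParams | None = None,
    seed: int | None = None,
    with_dose: bool = True,
) -> PatientPair:
    """Build one deterministic FB/DIBH phantom pair.

    Guarantees (up to rasterization error): DIBH lung volume =
    ``expansion_factor`` x FB volume within 5%; DIBH lung mass = FB lung mass
    within 2% (exact rescaling before HU noise); the heart moves
    posterior-inferior, out of the tangential field.
    """
    params = _auto_place(params or PhantomParams())
    if seed is not None:
        params = replace(params, seed=int(seed))
    rng = np.random.default_rng(params.seed)
    grid = _make_grid(params)
    texture = _LungTexture(rng, params.density_texture, params.lung_half_axes)
    table = default_density_table()

    # one correction pass: match the carved DIBH/FB volume ratio to the
    # requested expansion factor (the heart carve removes more volume in DIBH)
    fb_probe = rasterize(_build_structures(params, "fb", grid), "left_lung", grid)
    dibh_probe = rasterize(_build_structures(params, "dibh", grid), "left_lung", grid)
    if fb_probe.voxel_count and dibh_probe.voxel_count:
        ratio = dibh_probe.volume_cm3 / fb_probe.volume_cm3
        params = replace(
            params, scale_adjust=(params.expansion_factor / ratio) ** (1.0 / 3.0)
        )
        # fixed-point correction: pick the translation so the measured mean
        # ground-truth displacement over the carved lung equals the request
        # (the scaling term and the heart blend both offset the raw mean)
        requested = np.array(
            [params.expansion_left_mm, -params.expansion_anterior_mm, -params.expansion_caudal_mm]
        )
        for _ in range(3):
            gt = _ground_truth_dvf(params, grid)
            measured = gt.displacements[fb_probe.values].mean(axis=0)
            params = replace(
                params,
                shift_adjust=tuple(np.asarray(params.shift_adjust) + requested - measured),
            )
        params = _auto_place(params)

    phases = {}
    fb_lung_mass = None
    for phase in ("fb", "dibh"):
        structures = _build_structures(params, phase, grid)
        masks = {name: rasterize(structures, name, grid) for name in ("body", "left_lung", "heart")}
        density, lung_mass = _density_volume(
            params, grid, masks, phase, texture, target_lung_mass_g=fb_lung_mass
        )
        if phase == "fb":
            fb_lung_mass = lung_mass
        hu = table.invert(density.values)
        hu = hu + rng.normal(0.0, params.noise_hu, grid.shape)
        ct = grid.with_values(hu, unit="HU")
        dose = generate_tangential_dose(ct, structures, params) if with_dose else None
        phases[phase] = PhantomPhase(ct=ct, structures=structures, dose=dose, density=density)

    return PatientPair(
        fb=phases["fb"],
        dibh=phases["dibh"],
        ground_truth_dvf=_ground_truth_dvf(params, grid),
        params=params,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDistribution:
    """Normal distributions (mean, SD) for per-patient parameters.

    Defaults follow the cohort means/SDs the phantom emulates; samples are
    truncated to geometrically valid ranges.  ``adverse_fraction`` patients
    are built with the dense in-field DIBH patch.
    """

    lung_volume_cm3: Tuple[float, float] = (1432.0, 290.0)
    expansion_factor: Tuple[float, float] = (1.84, 0.26)
    lung_density: Tuple[float, float] = (0.31, 0.05)
    expansion_left_mm: Tuple[float, float] = (1.5, 2.4)
    expansion_anterior_mm: Tuple[float, float] = (16.0, 4.0)
    expansion_caudal_mm: Tuple[float, float] = (12.2, 4.6)
    ptv_half_z_mm: Tuple[float, float] = (55.0, 12.0)
    heart_coupling: float = 0.25  # extra heart displacement per mm of anterior expansion
    adverse_fraction: float = 4.0 / 31.0

    def _trunc(self, rng, mean_sd, lo, hi):
        value = rng.normal(*mean_sd)
        return float(np.clip(value, lo, hi))

    def sample(self, rng: np.random.Generator, base: PhantomParams, adverse: bool) -> PhantomParams:
        anterior = self._trunc(rng, self.expansion_anterior_mm, 8.0, 26.0)
        caudal = self._trunc(rng, self.expansion_caudal_mm, 2.0, 24.0)
        # adverse pairs keep a normal expansion; their mass gain comes from
        # the dense in-field patch, not from weak expansion
        factor = self._trunc(rng, self.expansion_factor, 1.5, 1.95)
        heart_dy = self.heart_coupling * anterior
        return replace(
            base,
            lung_volume_cm3=self._trunc(rng, self.lung_volume_cm3, 1000.0, 1750.0),
            expansion_factor=factor,
            lung_density=self._trunc(rng, self.lung_density, 0.2, 0.45),
            expansion_left_mm=self._trunc(rng, self.expansion_left_mm, -4.0, 7.0),
            expansion_anterior_mm=anterior,
            expansion_caudal_mm=caudal,
            ptv_half_z_mm=self._trunc(rng, self.ptv_half_z_mm, 35.0, 75.0),
            heart_displacement=(0.0, heart_dy, -heart_dy),
            adverse=adverse,
        )


def generate_cohort(
    n: int,
    params_distribution: CohortDistribution | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> List[PatientPair]:
    """Sample ``n`` reproducible phantom pairs from the cohort distribution."""
    if n < 2:
        raise ParameterError("cohort needs n >= 2")
    dist = params_distribution or CohortDistribution()
    if not (0.0 <= dist.adverse_fraction <= 1.0):
        raise ParameterError("adverse_fraction must lie in [0, 1]")
    base = base_params or PhantomParams()
    rng = np.random.default_rng(seed)
    n_adverse = int(round(dist.adverse_fraction * n))
    adverse_idx = set(rng.choice(n, size=n_adverse, replace=False).tolist())
    pairs = []
    for i in range(n):
        params = dist.sample(rng, base, adverse=i in adverse_idx)
        params = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        pairs.append(generate_pair(params))
    return pairs
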