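import numpy as np
import pytest

from dosemass.errors import EmptyStructureError, GeometryError
from dosemass.io_formats.types import Mask, VoxelGrid
from dosemass.registration import (
    DeformationField,
    default_schedule,
    expansion_metrics,
    intensity_match,
    merge_dvf,
    register_deformable,
    split_tissue,
    warp_mask,
)


def sphere_grid(shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0), center=(0, 0, 0), r=18.0):
    ax = [np.arange(s) * p - (s - 1) * p / 2 for s, p in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r * r
    values = np.where(inside, 0.0, -1000.0)
    origin = tuple(a[0] for a in ax)
    return VoxelGrid(values, spacing, origin, "HU"), Mask(inside, spacing, origin)


def constant_field(shape, vec, spacing=(2.0, 2.0, 2.0), origin=(0, 0, 0)):
    d = np.broadcast_to(np.asarray(vec, float), tuple(shape) + (3,)).copy()
    return DeformationField(d, spacing, origin)


class TestSplitTissue:
    def test_values_and_partition(self):
        ct, mask = sphere_grid()
        lung, nonlung = split_tissue(ct, mask, fill_hu=-1000.0)
        assert np.all(lung.values[mask.values] == ct.values[mask.values])
        assert np.all(lung.values[~mask.values] == -1000.0)
        assert np.all(nonlung.values[mask.values] == -1000.0)
        # partition: each voxel belongs to exactly one side
        assert np.all((lung.values == -1000.0) | (nonlung.values == -1000.0))

    def test_fill_value_configurable_and_echoed(self):
        ct, mask = sphere_grid()
        lung, nonlung = split_tissue(ct, mask, fill_hu=-500.0)
        assert lung.fill_hu == -500.0
        assert nonlung.fill_hu == -500.0
        assert np.all(lung.values[~mask.values] == -500.0)

    def test_empty_mask_raises(self):
        ct, mask = sphere_grid()
        empty = Mask(np.zeros(ct.shape, dtype=bool), ct.spacing, ct.origin)
        with pytest.raises(EmptyStructureError):
            split_tissue(ct, empty)


class TestRegister:
    def test_identity_registration(self):
        ct, _ = sphere_grid()
        dvf = register_deformable(ct, ct, stages=3)
        assert np.abs(dvf.magnitude()).mean() < 0.1

    def test_translation_recovery(self):
        fixed, mask = sphere_grid()
        moving, _ = sphere_grid(center=(0, -10.0, 0))  # 10 mm anterior
        dvf = register_deformable(fixed, moving)
        em = expansion_metrics(dvf, mask)
        assert em.mean_anterior == pytest.approx(10.0, abs=1.0)
        assert abs(em.mean_left) < 1.0
        assert abs(em.mean_caudal) < 1.0

    def test_final_mse_not_worse_than_identity(self):
        rng = np.random.default_rng(0)
        fixed = VoxelGrid(rng.normal(size=(16, 16, 16)), (2, 2, 2), (0, 0, 0), "HU")
        moving = VoxelGrid(rng.normal(size=(16, 16, 16)), (2, 2, 2), (0, 0, 0), "HU")
        dvf = register_deformable(fixed, moving, stages=2, max_iterations=10)
        diag = dvf.diagnostics[-1]
        assert diag["final_mse"] <= diag["identity_mse"] + 1e-9

    def test_schedule_validation(self):
        with pytest.raises(GeometryError):
            default_schedule(0)

    def test_diagnostics_recorded(self):
        ct, _ = sphere_grid(shape=(16, 16, 16))
        dvf = register_deformable(ct, ct, stages=2, max_iterations=5)
        stages = [d for d in dvf.diagnostics if "mse_after" in d]
        assert len(stages) >= 1

    def test_intensity_match_maps_levels(self):
        fixed, fmask = sphere_grid()
        moving = VoxelGrid(np.where(fmask.values, -500.0, -1000.0), fixed.spacing, fixed.origin, "HU")
        a, b = intensity_match(fixed, fmask, moving, fmask)
        assert a * -500.0 + b == pytest.approx(0.0)
        assert a * -1000.0 + b == pytest.approx(-1000.0)


class TestMergeDvf:
    def test_identical_fields_idempotent(self):
        _, mask = sphere_grid()
        f = constant_field(mask.shape, (1.0, -2.0, 3.0), mask.spacing, mask.origin)
        merged = merge_dvf(f, f, mask, band_voxels=3)
        np.testing.assert_allclose(merged.displacements, f.displacements)

    def test_band_zero_exact_piecewise(self):
        _, mask = sphere_grid()
        a = constant_field(mask.shape, (5.0, 0.0, 0.0), mask.spacing, mask.origin)
        b = constant_field(mask.shape, (0.0, 0.0, -5.0), mask.spacing, mask.origin)
        merged = merge_dvf(a, b, mask, band_voxels=0)
        np.testing.assert_array_equal(merged.displacements[mask.values], a.displacements[mask.values])
        np.testing.assert_array_equal(
            merged.displacements[~mask.values], b.displacements[~mask.values]
        )

    def test_band_convex_combination_and_symmetry(self):
        _, mask = sphere_grid()
        a = constant_field(mask.shape, (10.0, 0.0, 0.0), mask.spacing, mask.origin)
        b = constant_field(mask.shape, (0.0, 0.0, 0.0), mask.spacing, mask.origin)
        merged = merge_dvf(a, b, mask, band_voxels=3)
        x = merged.displacements[..., 0]
        assert np.all(x >= -1e-12) and np.all(x <= 10.0 + 1e-12)
        band = (x > 1e-9) & (x < 10.0 - 1e-9)
        assert band.any()  # a transition band exists
        # weights are symmetric about the interface: w(s) + w(-s) = 1, so the
        # first inside voxel and first outside voxel average to (A+B)/2
        from scipy.ndimage import distance_transform_edt

        din = distance_transform_edt(mask.values)
        dout = distance_transform_edt(~mask.values)
        inner = x[(din == 1.0)].mean()
        outer = x[(dout == 1.0)].mean()
        assert (inner + outer) / 2 == pytest.approx(5.0, abs=0.3)

    def test_geometry_mismatch_raises(self):
        _, mask = sphere_grid()
        a = constant_field(mask.shape, (1, 1, 1), mask.spacing, mask.origin)
        b = constant_field((8, 8, 8), (1, 1, 1), mask.spacing, mask.origin)
        with pytest.raises(GeometryError):
            merge_dvf(a, b, mask)


class TestWarpMask:
    def test_zero_field_identity(self):
        _, mask = sphere_grid()
        zero = constant_field(mask.shape, (0, 0, 0), mask.spacing, mask.origin)
        warped = warp_mask(mask, zero)
        np.testing.assert_array_equal(warped.values, mask.values)

    def test_translation_centroid_shift(self):
        # field maps fixed->moving: a moving-frame mask at +10 mm pulls back
        # onto the fixed-frame position; warping the *unshifted* mask through
        # the +10 mm field shifts its centroid by -10 mm.
        _, mask = sphere_grid(shape=(40, 40, 40))
        t = constant_field(mask.shape, (10.0, 0.0, 0.0), mask.spacing, mask.origin)
        warped = warp_mask(mask, t)
        shift = warped.centroid_mm() - mask.centroid_mm()
        assert shift[0] == pytest.approx(-10.0, abs=2.0)  # within one voxel
        assert abs(shift[1]) < 2.0 and abs(shift[2]) < 2.0

    def test_pullback_recovers_moving_frame_mask(self):
        _, fixed_mask = sphere_grid(shape=(40, 40, 40))
        _, moving_mask = sphere_grid(shape=(40, 40, 40), center=(10.0, 0, 0))
        t = constant_field(fixed_mask.shape, (10.0, 0.0, 0.0), fixed_mask.spacing, fixed_mask.origin)
        warped = warp_mask(moving_mask, t)
        inter = (warped.values & fixed_mask.values).sum()
        dice = 2 * inter / (warped.voxel_count + fixed_mask.voxel_count)
        assert dice > 0.95


class TestExpansionMetrics:
    def test_hand_computed_norm_and_index(self):
        _, mask = sphere_grid()
        # (left, anterior, caudal) = (1.5, 16.0, 12.2): stored components are
        # (+left, +posterior, +superior) so anterior/caudal flip sign
        f = constant_field(mask.shape, (1.5, -16.0, -12.2), mask.spacing, mask.origin)
        em = expansion_metrics(f, mask)
        assert em.mean_left == pytest.approx(1.5)
        assert em.mean_anterior == pytest.approx(16.0)
        assert em.mean_caudal == pytest.approx(12.2)
        assert em.expansion_3d == pytest.approx(np.sqrt(1.5**2 + 16.0**2 + 12.2**2))
        assert em.expansion_3d == pytest.approx(20.18, abs=0.01)
        assert em.breathing_index == pytest.approx((12.2 - 16.0) / 16.0 * 100.0)
        assert em.breathing_index == pytest.approx(-23.75)

    def test_zero_field(self):
        _, mask = sphere_grid()
        em = expansion_metrics(constant_field(mask.shape, (0, 0, 0), mask.spacing, mask.origin), mask)
        assert em.expansion_3d == 0.0
        assert not em.breathing_index_defined
        assert np.isnan(em.breathing_index)

    def test_equal_anterior_caudal_zero_index(self):
        _, mask = sphere_grid()
        em = expansion_metrics(
            constant_field(mask.shape, (0.0, -8.0, -8.0), mask.spacing, mask.origin), mask
        )
        assert em.breathing_index == pytest.approx(0.0)

    def test_anterior_dominant_negative_index(self):
        _, mask = sphere_grid()
        em = expansion_metrics(
            constant_field(mask.shape, (0.0, -16.0, -8.0), mask.spacing, mask.origin), mask
        )
        assert em.breathing_index < 0  # chest-dominant breathing

    def test_mean_of_norms_vs_norm_of_means(self):
        _, mask = sphere_grid()
        d = np.zeros(mask.shape + (3,))
        d[..., 0] = np.where(np.arange(mask.shape[0])[:, None, None] % 2 == 0, 10.0, -10.0)
        em = expansion_metrics(DeformationField(d, mask.spacing, mask.origin), mask)
        assert em.expansion_3d_mean_of_norms == pytest.approx(10.0)
        assert em.expansion_3d < 2.0  # norm of means nearly cancels

    def test_empty_mask_raises(self):
        _, mask = sphere_grid()
        empty = Mask(np.zeros(mask.shape, dtype=bool), mask.spacing, mask.origin)
        with pytest.raises(EmptyStructureError):
            expansion_metrics(constant_field(mask.shape, (0, 0, 0), mask.spacing, mask.origin), empty)
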