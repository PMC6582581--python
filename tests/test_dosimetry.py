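import numpy as np
import pytest

from dosemass.dosimetry import compute_dmh, compute_dvh, metrics, resample_to_grid
from dosemass.errors import DataError, EmptyStructureError, GeometryError
from dosemass.io_formats.types import Mask, VoxelGrid

from conftest import make_dose, make_mask


def brute_force_metrics(dose, mask, density, levels):
    """Independent per-voxel loop oracle for Dmean/Vx/Mx."""
    vv = mask.voxel_volume_cm3
    doses, rhos = [], []
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask.values[i, j, k]:
                    doses.append(dose.values[i, j, k])
                    rhos.append(density.values[i, j, k] if density is not None else None)
    n = len(doses)
    out = {
        "volume": n * vv,
        "dmean_volume": sum(doses) / n,
        "vx_rel": {},
        "vx_abs": {},
        "mx_rel": {},
        "mx_abs": {},
    }
    if density is not None:
        masses = [r * vv for r in rhos]
        out["mass"] = sum(masses)
        out["dmean_mass"] = sum(m * d for m, d in zip(masses, doses)) / out["mass"]
    for level in levels:
        hits = [idx for idx, d in enumerate(doses) if d >= level]
        out["vx_abs"][level] = len(hits) * vv
        out["vx_rel"][level] = 100.0 * len(hits) * vv / out["volume"]
        if density is not None:
            m_abs = sum(rhos[idx] * vv for idx in hits)
            out["mx_abs"][level] = m_abs
            out["mx_rel"][level] = 100.0 * m_abs / out["mass"]
    return out


class TestResample:
    def test_constant_preserved_on_finer_grid(self):
        src = VoxelGrid(np.full((4, 4, 4), 50.0), (5.0, 5.0, 5.0), (0, 0, 0), "Gy")
        tgt = VoxelGrid(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0), (0.5, 0.5, 0.5), "Gy")
        out = resample_to_grid(src, tgt)
        np.testing.assert_allclose(out.values, 50.0)

    def test_linear_ramp_exact(self):
        src_x = np.arange(6) * 4.0
        src = VoxelGrid(np.broadcast_to(src_x[:, None, None], (6, 4, 4)).copy(), (4, 4, 4), (0, 0, 0), "Gy")
        tgt = VoxelGrid(np.zeros((10, 3, 3)), (2.0, 4.0, 4.0), (1.0, 0.0, 0.0), "Gy")
        out = resample_to_grid(src, tgt)
        expected = (1.0 + 2.0 * np.arange(10)) / 4.0 * 4.0  # d(x) = x
        np.testing.assert_allclose(out.values[:, 0, 0], expected, atol=1e-12)

    def test_outside_target_zero_and_counted(self):
        src = VoxelGrid(np.full((3, 3, 3), 10.0), (1.0, 1.0, 1.0), (0, 0, 0), "Gy")
        tgt = VoxelGrid(np.zeros((3, 3, 6)), (1.0, 1.0, 1.0), (0, 0, 0), "Gy")
        out = resample_to_grid(src, tgt)
        assert np.all(out.values[:, :, 3:] == 0.0)
        assert out.outside_count == 3 * 3 * 3

    def test_disjoint_extents_raise(self):
        src = VoxelGrid(np.ones((3, 3, 3)), (1, 1, 1), (0, 0, 0), "Gy")
        tgt = VoxelGrid(np.ones((3, 3, 3)), (1, 1, 1), (100, 100, 100), "Gy")
        with pytest.raises(GeometryError):
            resample_to_grid(src, tgt)


class TestHistograms:
    def test_three_voxel_dvh(self, three_voxel_case):
        dose, density, mask = three_voxel_case
        dvh = compute_dvh(dose, mask, bin_width=1.0)
        assert dvh.total == pytest.approx(3.0)
        k20 = np.searchsorted(dvh.bin_edges, 20.0)
        assert dvh.cumulative[k20] == pytest.approx(2.0)

    def test_three_voxel_dmh(self, three_voxel_case):
        dose, density, mask = three_voxel_case
        dmh = compute_dmh(dose, mask, density, bin_width=1.0)
        assert dmh.total == pytest.approx(0.6)
        k20 = np.searchsorted(dmh.bin_edges, 20.0)
        assert dmh.cumulative[k20] == pytest.approx(0.5)
        assert 100.0 * dmh.cumulative[k20] / dmh.total == pytest.approx(83.33, abs=0.01)

    def test_uniform_dose_step(self):
        dose = make_dose(np.full((3, 3, 3), 50.0))
        mask = make_mask(np.ones((3, 3, 3)))
        dvh = compute_dvh(dose, mask, bin_width=1.0)
        below = dvh.bin_edges <= 50.0
        np.testing.assert_allclose(dvh.cumulative[below], dvh.total)
        np.testing.assert_allclose(dvh.cumulative[~below], 0.0)

    def test_zero_dose(self):
        dose = make_dose(np.zeros((2, 2, 2)))
        mask = make_mask(np.ones((2, 2, 2)))
        dvh = compute_dvh(dose, mask, bin_width=0.5)
        assert dvh.total == pytest.approx(8.0)
        assert np.all(dvh.cumulative[1:] == 0.0)

    def test_uniform_density_proportionality(self, rng):
        dose = make_dose(rng.uniform(0, 50, (5, 5, 5)))
        mask = make_mask(rng.random((5, 5, 5)) > 0.4)
        rho = 0.31
        density = VoxelGrid(np.full((5, 5, 5), rho), dose.spacing, dose.origin, "g/cm3")
        dvh = compute_dvh(dose, mask, 0.5)
        dmh = compute_dmh(dose, mask, density, 0.5)
        np.testing.assert_allclose(dmh.cumulative, rho * dvh.cumulative, rtol=1e-12)

    def test_monotone_nonincreasing(self, rng):
        dose = make_dose(rng.uniform(0, 50, (6, 6, 6)))
        mask = make_mask(np.ones((6, 6, 6)))
        density = VoxelGrid(rng.uniform(0.1, 1.2, (6, 6, 6)), dose.spacing, dose.origin, "g/cm3")
        for h in (compute_dvh(dose, mask, 0.1), compute_dmh(dose, mask, density, 0.1)):
            assert np.all(np.diff(h.cumulative) <= 1e-12)
            assert h.cumulative[0] == pytest.approx(h.total)

    def test_empty_mask_raises(self):
        dose = make_dose(np.ones((2, 2, 2)))
        mask = make_mask(np.zeros((2, 2, 2)))
        with pytest.raises(EmptyStructureError):
            compute_dvh(dose, mask)

    def test_negative_density_raises(self):
        dose = make_dose(np.ones((2, 2, 2)))
        mask = make_mask(np.ones((2, 2, 2)))
        density = VoxelGrid(np.full((2, 2, 2), -0.1), dose.spacing, dose.origin, "g/cm3")
        with pytest.raises(DataError):
            compute_dmh(dose, mask, density)

    def test_zero_density_metrics_raise(self):
        dose = make_dose(np.ones((2, 2, 2)))
        mask = make_mask(np.ones((2, 2, 2)))
        density = VoxelGrid(np.zeros((2, 2, 2)), dose.spacing, dose.origin, "g/cm3")
        dmh = compute_dmh(dose, mask, density)
        assert dmh.total == 0.0
        with pytest.raises(EmptyStructureError):
            metrics(dose, mask, density=density, dose_levels=[1.0])

    def test_misaligned_raises(self):
        dose = make_dose(np.ones((2, 2, 2)))
        mask = Mask(np.ones((2, 2, 2), dtype=bool), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            compute_dvh(dose, mask)

    def test_csv_export(self, three_voxel_case, tmp_path):
        dose, density, mask = three_voxel_case
        dvh = compute_dvh(dose, mask, bin_width=1.0)
        path = tmp_path / "dvh.csv"
        dvh.to_csv(str(path))
        header = path.read_text().splitlines()[0]
        assert header == "dose_gy,cumulative_cm3,relative_pct"


class TestMetrics:
    def test_three_voxel_worked_example(self, three_voxel_case):
        dose, density, mask = three_voxel_case
        m = metrics(dose, mask, density=density, dose_levels=[20.0])
        assert m.dmean_volume == pytest.approx(20.0)
        assert m.dmean_mass == pytest.approx((0.1 * 10 + 0.2 * 20 + 0.3 * 30) / 0.6)
        assert m.vx_rel[20.0] == pytest.approx(200.0 / 3.0, abs=1e-9)
        assert m.mx_rel[20.0] == pytest.approx(500.0 / 6.0, abs=1e-9)

    def test_identity_invariants(self, three_voxel_case):
        dose, density, mask = three_voxel_case
        m = metrics(dose, mask, density=density, dose_levels=[10.0, 20.0, 30.0])
        for level in (10.0, 20.0, 30.0):
            assert m.vx_abs[level] == pytest.approx(m.vx_rel[level] / 100.0 * m.volume_cm3)
            assert m.mx_abs[level] == pytest.approx(m.mx_rel[level] / 100.0 * m.mass_g)
        assert m.mean_density_g_cm3 * m.volume_cm3 == pytest.approx(m.mass_g, rel=1e-9)

    def test_uniform_density_equivalence(self, rng):
        dose = make_dose(rng.uniform(0, 50, (6, 6, 6)))
        mask = make_mask(rng.random((6, 6, 6)) > 0.3)
        density = VoxelGrid(np.full((6, 6, 6), 0.17), dose.spacing, dose.origin, "g/cm3")
        levels = [5.0, 20.0, 45.0]
        m = metrics(dose, mask, density=density, dose_levels=levels)
        assert m.dmean_mass == pytest.approx(m.dmean_volume, rel=1e-9)
        for level in levels:
            assert m.mx_rel[level] == pytest.approx(m.vx_rel[level], rel=1e-9)

    def test_oracle_equivalence_random_grids(self, rng):
        levels = [5.0, 10.0, 20.0, 30.0]
        for _ in range(5):
            shape = tuple(rng.integers(2, 7, 3))
            dose = make_dose(rng.uniform(0, 50, shape), spacing=(2.5, 2.5, 3.0))
            mask = make_mask(rng.random(shape) > 0.3, spacing=(2.5, 2.5, 3.0))
            if mask.voxel_count == 0:
                continue
            density = VoxelGrid(rng.uniform(0.05, 1.2, shape), dose.spacing, dose.origin, "g/cm3")
            m = metrics(dose, mask, density=density, dose_levels=levels)
            oracle = brute_force_metrics(dose, mask, density, levels)
            assert m.dmean_volume == pytest.approx(oracle["dmean_volume"], rel=1e-12)
            assert m.dmean_mass == pytest.approx(oracle["dmean_mass"], rel=1e-12)
            for level in levels:
                assert m.vx_abs[level] == oracle["vx_abs"][level]
                assert m.mx_rel[level] == pytest.approx(oracle["mx_rel"][level], rel=1e-12)

    def test_vx_monotone_in_level(self, rng):
        dose = make_dose(rng.uniform(0, 50, (6, 6, 6)))
        mask = make_mask(np.ones((6, 6, 6)))
        levels = [float(x) for x in range(0, 50, 5)]
        m = metrics(dose, mask, dose_levels=levels)
        vals = [m.vx_rel[level] for level in levels]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_negative_level_raises(self, three_voxel_case):
        dose, density, mask = three_voxel_case
        with pytest.raises(DataError):
            metrics(dose, mask, dose_levels=[-1.0])
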