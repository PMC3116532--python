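"""Density synthesis, cross-correlation and map I/O."""

import numpy as np
import pytest

from mdmdfit.density import (DensityMap, GridMismatchError, KernelParams,
                             cross_correlation, default_grid, read_map,
                             resample, simulate_density, write_map)

from conftest import toy_structure


def single_atom(pos=(0.0, 0.0, 0.0)):
    return toy_structure([pos])


@pytest.fixture()
def fine_grid():
    return DensityMap(np.array([-10.0] * 3), 0.5, np.zeros((40, 40, 40)))


class TestKernelParams:
    def test_cutoff_defaults_to_two_sigma(self):
        k = KernelParams(sigma=3.0)
        assert k.cutoff_radius == 6.0

    def test_sigma_from_resolution_is_half(self):
        k = KernelParams.from_resolution(8.0)
        assert k.sigma == 4.0
        assert k.cutoff_radius == 8.0  # 2 sigma == nominal resolution

    @pytest.mark.parametrize("kwargs", [dict(sigma=0.0), dict(sigma=-1.0),
                                        dict(sigma=1.0, cutoff_radius=-2.0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KernelParams(**kwargs)


class TestSimulateDensity:
    def test_empty_structure_gives_zero_map(self, fine_grid):
        empty = toy_structure(np.empty((0, 3)))
        out = simulate_density(empty, fine_grid, KernelParams(sigma=2.0))
        assert out.total_mass() == 0.0

    def test_outside_structure_warns_and_zeroes(self, fine_grid):
        far = single_atom((500.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="outside"):
            out = simulate_density(far, fine_grid, KernelParams(sigma=2.0))
        assert out.total_mass() == 0.0

    def test_voxel_integrals_match_fine_midpoint_quadrature(self, fine_grid):
        """Exact erf voxel integrals vs midpoint rule at 10x resolution."""
        kernel = KernelParams(sigma=4.0)
        atom = single_atom((0.3, -0.2, 0.1))  # off-center on purpose
        out = simulate_density(atom, fine_grid, kernel)
        # midpoint quadrature: subdivide each voxel 10x per axis
        sub = 10
        n = fine_grid.shape[0]
        s = fine_grid.spacing[0]
        centers = fine_grid.origin[0] + (np.arange(n * sub) + 0.5) * (s / sub)
        dx = centers - 0.3
        dy = centers - (-0.2)
        dz = centers - 0.1
        a = kernel.alpha
        gx = np.exp(-a * dx ** 2).reshape(n, sub).sum(axis=1) * (s / sub)
        gy = np.exp(-a * dy ** 2).reshape(n, sub).sum(axis=1) * (s / sub)
        gz = np.exp(-a * dz ** 2).reshape(n, sub).sum(axis=1) * (s / sub)
        quad = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        # apply the same voxel-center cutoff mask
        cx = fine_grid.voxel_centers_1d(0)
        d2 = ((cx - 0.3)[:, None, None] ** 2
              + (cx + 0.2)[None, :, None] ** 2
              + (cx - 0.1)[None, None, :] ** 2)
        quad[d2 > kernel.cutoff_radius ** 2] = 0.0
        assert out.total_mass() == pytest.approx(quad.sum(), rel=0.01)
        assert np.abs(out.values - quad).max() < 0.01 * quad.max()

    def test_translation_equivariance_by_one_voxel(self, fine_grid):
        kernel = KernelParams(sigma=2.0)
        a = simulate_density(single_atom((0, 0, 0)), fine_grid, kernel)
        s = fine_grid.spacing[0]
        b = simulate_density(single_atom((s, 0, 0)), fine_grid, kernel)
        np.testing.assert_allclose(b.values[1:], a.values[:-1], atol=1e-12)

    def test_atom_order_permutation_invariance(self, fine_grid, rng):
        coords = rng.normal(0, 3, size=(10, 3))
        kernel = KernelParams(sigma=2.0)
        a = simulate_density(toy_structure(coords), fine_grid, kernel)
        perm = rng.permutation(10)
        b = simulate_density(toy_structure(coords[perm]), fine_grid, kernel)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_doubling_cutoff_changes_mass_below_tail_bound(self, fine_grid):
        # mass beyond 2 sigma of the 3-D Gaussian is ~1.1%
        a = simulate_density(single_atom(), fine_grid,
                             KernelParams(sigma=3.0))
        b = simulate_density(single_atom(), fine_grid,
                             KernelParams(sigma=3.0, cutoff_radius=12.0))
        rel = (b.total_mass() - a.total_mass()) / b.total_mass()
        assert 0.0 <= rel < 0.012

    def test_default_grid_covers_structure(self, trna90):
        kernel = KernelParams.from_resolution(8.0)
        grid = default_grid(trna90, kernel)
        assert np.all(grid.origin <= trna90.coords.min(axis=0))
        out = simulate_density(trna90, grid, kernel)
        assert out.total_mass() > 0


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, fine_grid, rng):
        m = DensityMap(fine_grid.origin, fine_grid.spacing,
                       rng.random(fine_grid.shape))
        assert cross_correlation(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_is_zero(self):
        a = np.zeros((4, 4, 4)); a[:2] = 1.0
        b = np.zeros((4, 4, 4)); b[2:] = 1.0
        ma = DensityMap([0, 0, 0], 1.0, a)
        mb = DensityMap([0, 0, 0], 1.0, b)
        assert cross_correlation(ma, mb) == 0.0

    def test_two_voxel_hand_computed_value(self):
        ma = DensityMap([0, 0, 0], 1.0, np.array([[[1.0, 0.0]]]))
        mb = DensityMap([0, 0, 0], 1.0, np.array([[[1.0, 1.0]]]))
        assert cross_correlation(ma, mb) == pytest.approx(1 / np.sqrt(2),
                                                          abs=1e-12)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e6])
    def test_scale_invariance(self, scale, rng):
        a = DensityMap([0, 0, 0], 1.0, rng.random((5, 5, 5)))
        b = DensityMap([0, 0, 0], 1.0, rng.random((5, 5, 5)))
        scaled = DensityMap([0, 0, 0], 1.0, scale * a.values)
        assert cross_correlation(scaled, b) == pytest.approx(
            cross_correlation(a, b), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        a = DensityMap([0, 0, 0], 1.0, rng.random((6, 6, 6)))
        b = DensityMap([0, 0, 0], 1.0, rng.random((6, 6, 6)))
        cab = cross_correlation(a, b)
        assert cab == cross_correlation(b, a)
        assert 0.0 <= cab <= 1.0

    def test_geometry_mismatch_instructs_resampling(self, rng):
        a = DensityMap([0, 0, 0], 1.0, rng.random((4, 4, 4)))
        b = DensityMap([1, 0, 0], 1.0, rng.random((4, 4, 4)))
        with pytest.raises(GridMismatchError, match="resample"):
            cross_correlation(a, b)

    def test_mean_subtracted_variant_is_pearson(self, rng):
        a = DensityMap([0, 0, 0], 1.0, rng.random((5, 5, 5)))
        b = DensityMap([0, 0, 0], 1.0, rng.random((5, 5, 5)))
        pearson = cross_correlation(a, b, mean_subtract=True)
        expected = np.corrcoef(a.values.ravel(), b.values.ravel())[0, 1]
        assert pearson == pytest.approx(expected, abs=1e-12)
        # default form does not subtract the mean
        assert pearson != pytest.approx(cross_correlation(a, b), abs=1e-3)

    def test_all_zero_map_rejected(self):
        z = DensityMap([0, 0, 0], 1.0, np.zeros((3, 3, 3)))
        m = DensityMap([0, 0, 0], 1.0, np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="zero"):
            cross_correlation(z, m)


class TestResample:
    def test_identity_geometry_is_exact(self, rng):
        m = DensityMap([1, 2, 3], 0.7, rng.random((5, 5, 5)))
        out = resample(m, m.geometry())
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_map_stays_constant_in_interior(self):
        m = DensityMap([0, 0, 0], 1.0, np.full((8, 8, 8), 2.5))
        tgt = DensityMap([2, 2, 2], 0.5, np.zeros((8, 8, 8)))
        out = resample(m, tgt)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_linear_ramp_is_reproduced_exactly(self):
        ramp = DensityMap([0, 0, 0], 1.0,
                          np.fromfunction(lambda i, j, k: i + 1.0, (10, 6, 6)))
        tgt = DensityMap([1, 1, 1], 0.5, np.zeros((8, 8, 8)))
        out = resample(ramp, tgt)
        x = tgt.voxel_centers_1d(0)
        expect = (x - 0.5) + 1.0  # analytic ramp through voxel centers
        assert np.abs(out.values - expect[:, None, None]).max() < 1e-9


class TestMapIO:
    def test_roundtrip_preserves_everything(self, tmp_path, rng):
        m = DensityMap([1.5, -2.0, 3.0], 0.8, rng.random((8, 8, 8)))
        path = tmp_path / "map.mrc"
        write_map(m, path)
        again = read_map(path)
        assert again.shape == m.shape
        np.testing.assert_allclose(again.origin, m.origin, atol=1e-5)
        np.testing.assert_allclose(again.spacing, m.spacing, atol=1e-6)
        np.testing.assert_allclose(again.values, m.values, atol=1e-6)

    def test_origin_offset_honored_in_comparison(self, tmp_path):
        """A map written at a shifted origin correlates perfectly with a map
        synthesized directly at that origin."""
        kernel = KernelParams(sigma=2.0)
        grid_a = DensityMap([5.0, 0.0, 0.0], 0.5, np.zeros((24, 24, 24)))
        atom = toy_structure([[11.0, 6.0, 6.0]])
        direct = simulate_density(atom, grid_a, kernel)
        path = tmp_path / "shifted.mrc"
        write_map(direct, path)
        again = read_map(path)
        resynth = simulate_density(atom, again.geometry(), kernel)
        assert cross_correlation(again, resynth) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_map(tmp_path / "nope.mrc")


class TestDensityMapInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DensityMap([0, 0, 0], 1.0, -np.ones((2, 2, 2)))

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            DensityMap([0, 0, 0], 0.0, np.ones((2, 2, 2)))
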