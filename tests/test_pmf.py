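"""Grid geometry, thermodynamic integration, relaxation, and the direct-solve oracle."""

import numpy as np
import pytest

from pmfsurf.errors import DomainError, PmfsurfError
from pmfsurf.pmf import (
    BoundaryCondition,
    FreeEnergySurface,
    GradientField,
    GridSpec,
    line_integrate_x,
    oracle_least_squares,
    refine_fine_grid,
    relax_surface,
    set_boundaries,
    torque_integrate_check,
)
from pmfsurf.synth import NoiseSpec, sample_gradient_field
from pmfsurf import benchmark as B


def _zero_field(grid):
    return GradientField(grid=grid, fx=np.zeros(grid.shape), Tz=np.zeros(grid.shape))


class TestGridSpec:
    def test_coarse_grid_node_count(self, coarse_grid):
        assert coarse_grid.shape == (13, 12)

    def test_fine_grid_node_count(self, fine_grid):
        assert fine_grid.shape == (16, 16)
        assert fine_grid.nx * fine_grid.ntheta == 256

    def test_indivisible_spacing_rejected(self):
        with pytest.raises(PmfsurfError):
            GridSpec(0.0, 10.0, 3.0, 0.0, 30.0, 15.0)

    def test_periodic_range_must_cover_one_period(self):
        with pytest.raises(PmfsurfError):
            GridSpec(0.0, 10.0, 5.0, 0.0, 90.0, 15.0, theta_periodic=True)

    def test_node_positions(self, coarse_grid):
        assert coarse_grid.x_nodes[0] == -30.0 and coarse_grid.x_nodes[-1] == 30.0
        assert coarse_grid.theta_nodes[-1] == 165.0  # duplicate endpoint excluded


class TestLineIntegration:
    def test_constant_force(self, coarse_grid):
        field = _zero_field(coarse_grid)
        field.fx[:] = -1.0
        F = line_integrate_x(field, 0)
        assert F[0] == 0.0
        assert F[-1] == pytest.approx(60.0)

    def test_zero_force_flat(self, coarse_grid):
        F = line_integrate_x(_zero_field(coarse_grid), 3)
        np.testing.assert_array_equal(F, 0.0)

    def test_quadratic_surface_recovered(self):
        # F = a x^2 has a linear gradient, integrated exactly by the trapezoid
        grid = GridSpec(-10.0, 10.0, 2.0, 0.0, 30.0, 15.0)
        a = 0.37
        field = _zero_field(grid)
        field.fx[:] = np.tile((-2.0 * a * grid.x_nodes)[:, None], (1, grid.ntheta))
        F = line_integrate_x(field, 0)
        expected = a * grid.x_nodes**2 - a * grid.x_min**2
        np.testing.assert_allclose(F, expected, atol=1e-10)


class TestSetBoundaries:
    def test_mean_of_row_integrals(self):
        grid = GridSpec(0.0, 1.0, 1.0, 0.0, 30.0, 15.0)  # 2 x nodes, 3 theta rows
        field = _zero_field(grid)
        field.fx[:, 0] = -1.0
        field.fx[:, 1] = -2.0
        field.fx[:, 2] = -3.0
        bc = set_boundaries(field)
        assert bc.dFw2o == pytest.approx(2.0)

    def test_identical_rows_give_exact_value(self, coarse_grid):
        field = _zero_field(coarse_grid)
        field.fx[:] = -0.5
        assert set_boundaries(field).dFw2o == pytest.approx(30.0)


class TestRelaxation:
    def test_zero_field_zero_boundaries(self, coarse_grid):
        field = _zero_field(coarse_grid)
        bc = set_boundaries(field)
        surface = relax_surface(field, bc, sweep_mode="ordered")
        np.testing.assert_allclose(surface.F, 0.0, atol=1e-12)

    def test_exact_gradients_recover_planted_surface(self, three_well_surface, coarse_grid):
        field, truth = sample_gradient_field(three_well_surface, coarse_grid)
        surface = relax_surface(field, set_boundaries(field), tol=1e-10, sweep_mode="ordered")
        assert np.abs(surface.F - truth.F).max() < 1e-8

    def test_noisy_field_matches_direct_solve(self, three_well_surface, coarse_grid):
        noise = NoiseSpec(sigma_f=1.0, sigma_T=1.0, n_samples=10_000, seed=5)
        field, _ = sample_gradient_field(three_well_surface, coarse_grid, noise)
        bc = set_boundaries(field)
        relaxed = relax_surface(field, bc, tol=1e-10, seed=1)
        direct = oracle_least_squares(field, bc)
        assert np.abs(relaxed.F - direct.F).max() < 1e-8

    def test_fixed_point_is_seed_and_sweep_invariant(self, three_well_surface, coarse_grid):
        noise = NoiseSpec(sigma_f=1.0, sigma_T=1.0, n_samples=10_000, seed=9)
        field, _ = sample_gradient_field(three_well_surface, coarse_grid, noise)
        bc = set_boundaries(field)
        a = relax_surface(field, bc, tol=1e-11, seed=1, sweep_mode="random")
        b = relax_surface(field, bc, tol=1e-11, seed=2, sweep_mode="random")
        c = relax_surface(field, bc, tol=1e-11, sweep_mode="ordered")
        assert np.abs(a.F - b.F).max() < 1e-8
        assert np.abs(a.F - c.F).max() < 1e-8

    def test_gauge_invariance_of_boundary_shift(self, three_well_surface, coarse_grid):
        noise = NoiseSpec(sigma_f=1.0, sigma_T=1.0, n_samples=10_000, seed=2)
        field, _ = sample_gradient_field(three_well_surface, coarse_grid, noise)
        bc = set_boundaries(field)
        shifted = BoundaryCondition(
            x_min_values=bc.x_min_values + 7.5,
            x_max_values=bc.x_max_values + 7.5,
            dFw2o=bc.dFw2o,
        )
        base = oracle_least_squares(field, bc)
        moved = oracle_least_squares(field, shifted)
        np.testing.assert_allclose(moved.F - base.F, 7.5, atol=1e-8)

    def test_rmse_scales_with_sampling(self, three_well_surface, coarse_grid):
        """Gradient sem σ/√n: 100x more samples → ~10x smaller surface RMSE."""
        rmses = []
        for n in (100, 10_000):
            noise = NoiseSpec(sigma_f=1.0, sigma_T=1.0, n_samples=n, seed=4)
            field, truth = sample_gradient_field(three_well_surface, coarse_grid, noise)
            surface = relax_surface(field, set_boundaries(field), tol=1e-10,
                                    sweep_mode="ordered")
            rmses.append(np.sqrt(np.mean((surface.F - truth.F) ** 2)))
        ratio = rmses[0] / rmses[1]
        assert 4.0 < ratio < 25.0

    def test_nonconvergence_warns_and_returns(self, three_well_surface, coarse_grid):
        noise = NoiseSpec(sigma_f=1.0, sigma_T=1.0, n_samples=100, seed=8)
        field, _ = sample_gradient_field(three_well_surface, coarse_grid, noise)
        bc = set_boundaries(field)
        with pytest.warns(UserWarning, match="did not converge"):
            surface = relax_surface(field, bc, max_iter=300, tol=1e-14,
                                    sweep_mode="ordered")
        assert np.all(np.isfinite(surface.F))


class TestOracle:
    def test_three_by_three_zero_interior(self):
        grid = GridSpec(0.0, 2.0, 1.0, 0.0, 30.0, 15.0)
        field = _zero_field(grid)
        bc = set_boundaries(field)
        surface = oracle_least_squares(field, bc)
        np.testing.assert_allclose(surface.F, 0.0, atol=1e-12)

    def test_uniform_rows_reduce_to_cumulative_trapezoid(self, rng):
        """With zero torque and identical rows the 2D solve is the 1D integral."""
        grid = GridSpec(0.0, 8.0, 1.0, 0.0, 30.0, 15.0)
        fx_profile = rng.normal(size=grid.nx)
        field = GradientField(
            grid=grid, fx=np.tile(fx_profile[:, None], (1, grid.ntheta)),
            Tz=np.zeros(grid.shape),
        )
        bc = set_boundaries(field)
        surface = oracle_least_squares(field, bc)
        expected = line_integrate_x(field, 0)
        for j in range(grid.ntheta):
            np.testing.assert_allclose(surface.F[:, j], expected, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_field_fixed_point_equivalence(self, rng, seed):
        grid = GridSpec(0.0, 6.0, 1.0, 0.0, 180.0, 30.0, theta_periodic=True)
        gen = np.random.default_rng(seed)
        field = GradientField(grid=grid, fx=gen.normal(size=grid.shape),
                              Tz=gen.normal(size=grid.shape))
        bc = set_boundaries(field)
        relaxed = relax_surface(field, bc, tol=1e-11, seed=seed)
        direct = oracle_least_squares(field, bc)
        assert np.abs(relaxed.F - direct.F).max() < 1e-8


class TestTorqueCheck:
    def test_zero_torque_flat_profile(self, coarse_grid):
        profile, residual = torque_integrate_check(_zero_field(coarse_grid), 0)
        np.testing.assert_array_equal(profile, 0.0)
        assert residual == 0.0

    def test_consistent_field_closes(self, three_well_surface, coarse_grid):
        field, _ = sample_gradient_field(three_well_surface, coarse_grid)
        for i in range(coarse_grid.nx):
            _, residual = torque_integrate_check(field, i)
            assert residual < 1e-10

    def test_far_field_rows_are_torque_free(self, three_well_surface, coarse_grid):
        """⟨Tz⟩ at x = ±30 Å is essentially zero: flat θz profiles in both bulks."""
        field, _ = sample_gradient_field(three_well_surface, coarse_grid)
        for i in (0, coarse_grid.nx - 1):
            profile, _ = torque_integrate_check(field, i)
            assert np.abs(profile).max() < 1e-9


class TestRefineFineGrid:
    def test_planar_surface_refines_exactly(self):
        # F = a x is exactly integrable and bilinear interpolation is exact
        coarse = GridSpec(-30.0, 30.0, 5.0, 0.0, 180.0, 15.0, theta_periodic=True)
        fine = GridSpec(-25.0, -10.0, 1.0, 75.0, 150.0, 5.0)
        a = -0.8

        def plane_field(grid):
            fx = np.full(grid.shape, -a)
            return GradientField(grid=grid, fx=fx, Tz=np.zeros(grid.shape))

        cfield = plane_field(coarse)
        csurf = relax_surface(cfield, set_boundaries(cfield), tol=1e-12,
                              sweep_mode="ordered")
        fsurf = refine_fine_grid(csurf, plane_field(fine), tol=1e-12,
                                 sweep_mode="ordered")
        X = fine.x_nodes[:, None] * np.ones((1, fine.ntheta))
        truth = a * (X - coarse.x_min)
        assert np.abs(fsurf.F - truth).max() < 1e-6

    def test_subblock_consistency(self, rng):
        coarse = GridSpec(0.0, 8.0, 1.0, 0.0, 40.0, 5.0)
        field = GradientField(grid=coarse, fx=rng.normal(size=coarse.shape),
                              Tz=rng.normal(size=coarse.shape))
        csurf = oracle_least_squares(field, set_boundaries(field))
        fine = GridSpec(2.0, 6.0, 1.0, 10.0, 30.0, 5.0)
        i0 = 2
        j0 = 2
        ffield = GradientField(
            grid=fine,
            fx=field.fx[i0 : i0 + fine.nx, j0 : j0 + fine.ntheta],
            Tz=field.Tz[i0 : i0 + fine.nx, j0 : j0 + fine.ntheta],
        )
        fsurf = refine_fine_grid(csurf, ffield, tol=1e-12, sweep_mode="ordered")
        shared = csurf.F[i0 : i0 + fine.nx, j0 : j0 + fine.ntheta]
        assert np.abs(fsurf.F - shared).max() < 1e-8

    def test_out_of_domain_rejected(self, coarse_grid, three_well_surface):
        field, _ = sample_gradient_field(three_well_surface, coarse_grid)
        csurf = relax_surface(field, set_boundaries(field), tol=1e-8,
                              sweep_mode="ordered")
        beyond = GridSpec(-40.0, -10.0, 1.0, 75.0, 150.0, 5.0)
        ffield = _zero_field(beyond)
        with pytest.raises(DomainError):
            refine_fine_grid(csurf, ffield)


class TestSurfaceIO:
    def test_tsv_roundtrip_lossless(self, three_well_surface, coarse_grid, tmp_path):
        field, truth = sample_gradient_field(three_well_surface, coarse_grid)
        path = tmp_path / "F.tsv"
        truth.to_tsv(path)
        back = FreeEnergySurface.from_tsv(path, coarse_grid)
        np.testing.assert_array_equal(back.F, truth.F)
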