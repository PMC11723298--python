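"""Fourier-series field solution: coefficients, symmetries, derived fields."""

import math

import numpy as np
import pytest

from depfield import (
    DeviceGeometry,
    DriveSettings,
    GapApproximation,
    build_solution,
    coefficients_closed_form,
    coefficients_quadrature,
    field_grid,
    gap_potential,
    top_boundary_profile,
    uniform_lid_solution,
)


class TestGapPotential:
    def test_midpoint_is_half_vrms(self, type_a, drive, gap, gap_continuous):
        for g in (gap, gap_continuous):
            assert gap_potential(0.5, type_a, drive, g) == pytest.approx(
                drive.V_rms / 2)

    def test_antisymmetry(self, type_a, drive, gap, gap_continuous, rng):
        x = rng.uniform(0.2501, 0.7499, size=50)
        for g in (gap, gap_continuous):
            total = (gap_potential(x, type_a, drive, g)
                     + gap_potential(1.0 - x, type_a, drive, g))
            np.testing.assert_allclose(total, drive.V_rms, rtol=1e-12)

    def test_published_family_edge_value(self, type_a, drive, gap):
        """The published cubic is discontinuous: its edge limit is
        (V/pi)(pi/2 + C + (pi/2 - C)/6), about 0.78 V_rms, not V_rms."""
        C = gap.C
        expected = (drive.V_rms / math.pi) * (
            math.pi / 2 + C + (math.pi / 2 - C) / 6)
        val = gap_potential(0.25 + 1e-12, type_a, drive, gap)
        assert val == pytest.approx(expected, rel=1e-6)
        assert val < drive.V_rms

    def test_continuous_family_meets_electrode(self, type_a, drive,
                                               gap_continuous):
        """The edge-continuous variant equals V_rms / 0 at the gap edges for
        any C (here the canonical one)."""
        assert gap_potential(0.25 + 1e-12, type_a, drive,
                             gap_continuous) == pytest.approx(drive.V_rms,
                                                              rel=1e-9)
        assert abs(gap_potential(0.75 - 1e-12, type_a, drive,
                                 gap_continuous)) < 1e-9 * drive.V_rms

    def test_domain_error_outside_gap(self, type_a, drive, gap):
        for bad in (0.25, 0.75, 0.1, 0.9):
            with pytest.raises(ValueError):
                gap_potential(bad, type_a, drive, gap)


class TestTopBoundaryProfile:
    def test_piecewise_values(self, type_a, drive, gap):
        assert top_boundary_profile(0.0, type_a, drive, gap) == drive.V_rms
        assert top_boundary_profile(0.25, type_a, drive, gap) == drive.V_rms
        assert top_boundary_profile(1.0, type_a, drive, gap) == 0.0
        assert top_boundary_profile(0.8, type_a, drive, gap) == 0.0

    def test_mean_is_half_vrms(self, type_a, drive, gap):
        from scipy.integrate import quad
        val, _ = quad(lambda x: top_boundary_profile(x, type_a, drive, gap),
                      0, 1, points=[0.25, 0.75], limit=200)
        assert val == pytest.approx(drive.V_rms / 2, rel=1e-9)

    def test_out_of_range(self, type_a, drive, gap):
        with pytest.raises(ValueError):
            top_boundary_profile(1.2, type_a, drive, gap)


class TestCoefficients:
    @pytest.mark.parametrize("edge_continuous", [False, True])
    def test_closed_form_matches_quadrature(self, type_a, drive,
                                            edge_continuous):
        """Dual-path equivalence: analytic projection vs numerical projection
        of the boundary profile, to relative 1e-9 for n <= 200."""
        g = GapApproximation(edge_continuous=edge_continuous)
        cf = coefficients_closed_form(type_a, drive, g, 200)
        qd = coefficients_quadrature(type_a, drive, g, 200)
        assert cf.a0 == pytest.approx(qd.a0, rel=1e-11)
        n = np.arange(1, 201)
        odd = n % 2 == 1
        np.testing.assert_allclose(qd.a[odd], cf.a[odd], rtol=1e-9)
        # even harmonics vanish identically (boundary-data antisymmetry)
        assert np.max(np.abs(cf.a[~odd])) < 1e-12 * drive.V_rms
        assert np.max(np.abs(qd.a[~odd])) < 1e-12 * drive.V_rms

    def test_a0_is_half_vrms(self, small_solution, drive):
        assert small_solution.a0 == drive.V_rms / 2

    def test_coefficients_decay(self, type_a, drive, gap):
        sol = coefficients_closed_form(type_a, drive, gap, 5001)
        odd = np.arange(1, 5002) % 2 == 1
        head = np.max(np.abs(sol.a[odd][:50]))
        tail = np.max(np.abs(sol.a[odd][-50:]))
        assert tail < head / 50  # Riemann–Lebesgue: a_n -> 0

    def test_uniform_profile_override(self, type_a, drive, gap):
        """Degenerate check: a flat top plate yields a_n ~ 0 and the linear
        parallel-plate potential."""
        V = drive.V_rms
        sol = coefficients_quadrature(type_a, drive, gap, 50,
                                      profile=lambda x: np.full_like(x, V))
        assert sol.a0 == pytest.approx(V, rel=1e-12)
        assert np.max(np.abs(sol.a)) < 1e-12 * V


class TestPotential:
    def test_zero_at_lid(self, small_solution, rng):
        x = rng.uniform(0, 1, 20)
        np.testing.assert_array_equal(
            small_solution.potential(x, np.zeros_like(x)), 0.0)

    def test_mirror_identity(self, small_solution, drive, rng):
        """phi(x*,y*) + phi(1-x*,y*) = V_rms * y* (harmonic mirror sum has
        top data V_rms and lid data 0)."""
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0.05, 0.999, 30)
        total = (small_solution.potential(x, y)
                 + small_solution.potential(1.0 - x, y))
        np.testing.assert_allclose(total, drive.V_rms * y, atol=1e-10)

    def test_on_electrode_convergence(self, type_a, drive, gap):
        """At y*=1 on the electrode (away from the edge) the series converges
        to V_rms as the truncation grows."""
        errs = []
        for n in (100, 1000, 10_000):
            sol = build_solution(type_a, drive, gap=gap, n_terms=n)
            errs.append(abs(sol.potential(0.1, 1.0) - drive.V_rms))
        assert errs[2] < errs[0]
        assert errs[2] < 5e-3 * drive.V_rms

    def test_boundary_satisfaction_mean(self, type_a, drive, gap):
        """Mean reconstruction error of the top profile < 0.5 % of V_rms at
        n = 10,000 (Gibbs zones +-0.005 around each edge excluded)."""
        sol = build_solution(type_a, drive, gap=gap, n_terms=10_000)
        x = np.linspace(0, 1, 1000)
        keep = (np.abs(x - 0.25) > 0.005) & (np.abs(x - 0.75) > 0.005)
        recon = sol.potential(x[keep], np.ones(keep.sum()))
        target = top_boundary_profile(x[keep], type_a, drive, gap)
        assert np.mean(np.abs(recon - target)) < 0.005 * drive.V_rms

    def test_rejects_out_of_domain(self, small_solution):
        with pytest.raises(ValueError):
            small_solution.potential(1.5, 0.5)
        with pytest.raises(ValueError):
            small_solution.potential(0.5, -0.1)


class TestElectricField:
    def test_ex_vanishes_on_symmetry_planes(self, small_solution, type_a,
                                            drive, rng):
        y = rng.uniform(0.1, 0.99, 15)
        scale = drive.V_rms / type_a.H
        for x0 in (0.0, 1.0):
            Ex, _ = small_solution.electric_field(np.full_like(y, x0), y)
            np.testing.assert_allclose(Ex, 0.0, atol=1e-9 * scale)

    def test_matches_finite_differences_of_potential(self, small_solution,
                                                     type_a):
        h = 1e-6
        for (x0, y0) in [(0.37, 0.81), (0.6, 0.5), (0.12, 0.93)]:
            Ex, Ey = small_solution.electric_field(x0, y0)
            Ex_fd = -(small_solution.potential(x0 + h, y0)
                      - small_solution.potential(x0 - h, y0)) / (2 * h * type_a.L)
            Ey_fd = -(small_solution.potential(x0, y0 + h)
                      - small_solution.potential(x0, y0 - h)) / (2 * h * type_a.H)
            assert Ex == pytest.approx(Ex_fd, rel=1e-5)
            assert Ey == pytest.approx(Ey_fd, rel=1e-5)

    def test_parallel_plate_limit(self, type_a, drive):
        sol = uniform_lid_solution(type_a, drive)
        Ex, Ey = sol.electric_field(0.3, 0.6)
        assert Ex == 0.0
        assert Ey == pytest.approx(-drive.V_rms / type_a.H, rel=1e-14)
        assert abs(Ey) == pytest.approx(drive.V_rms / type_a.H, rel=1e-14)

    def test_normalization(self, small_solution, type_a, drive):
        Ex, Ey = small_solution.electric_field(0.3, 0.7)
        Exn, Eyn = small_solution.electric_field(0.3, 0.7, normalized=True)
        assert Exn == pytest.approx(Ex * type_a.H / drive.V_rms, rel=1e-14)
        assert Eyn == pytest.approx(Ey * type_a.H / drive.V_rms, rel=1e-14)


class TestGradESquared:
    def test_matches_finite_differences_of_intensity(self, small_solution,
                                                     type_a):
        h = 1e-6

        def E2(x, y):
            Ex, Ey = small_solution.electric_field(x, y)
            return Ex ** 2 + Ey ** 2

        for (x0, y0) in [(0.4, 0.8), (0.2, 0.95), (0.55, 0.6)]:
            Gx, Gy = small_solution.grad_E_squared(x0, y0)
            Gx_fd = (E2(x0 + h, y0) - E2(x0 - h, y0)) / (2 * h * type_a.L)
            Gy_fd = (E2(x0, y0 + h) - E2(x0, y0 - h)) / (2 * h * type_a.H)
            assert Gx == pytest.approx(Gx_fd, rel=1e-4)
            assert Gy == pytest.approx(Gy_fd, rel=1e-4)

    def test_x_component_small_at_gap_midline(self, small_solution):
        """Near the electrode plane the x-gradient of |E|^2 nearly cancels at
        the gap midline (the two edge contributions oppose).  The grounded
        lid breaks exact evenness of |E|^2 about x*=1/2 (its uniform-field
        contribution to Ey couples to the odd field part), so the zero is
        approximate and sharpens toward the plane."""
        for yv, tol in ((0.99, 1e-2), (0.998, 1e-4)):
            Gx, _ = small_solution.grad_E_squared(0.5, yv)
            edge = np.hypot(*small_solution.grad_E_squared(0.25, yv))
            assert abs(Gx) < tol * edge

    def test_edge_concentration(self, small_solution):
        """The force field is concentrated at the electrode edge: magnitude
        at x*=w/L exceeds the gap-midline value by >= 10x near the plane."""
        y = 0.995
        edge = np.hypot(*small_solution.grad_E_squared(0.25, y))
        mid = np.hypot(*small_solution.grad_E_squared(0.5, y))
        assert edge > 10 * mid


class TestDepForce:
    def test_quadratic_drive_scaling(self, type_a, gap):
        d1 = DriveSettings(V_rms=2.0)
        d2 = DriveSettings(V_rms=4.0)
        s1 = build_solution(type_a, d1, gap=gap, n_terms=300)
        s2 = build_solution(type_a, d2, gap=gap, n_terms=300)
        F1 = s1.dep_force(1e-24, 0.3, 0.9)
        F2 = s2.dep_force(1e-24, 0.3, 0.9)
        assert F2[0] == pytest.approx(4 * F1[0], rel=1e-10)
        assert F2[1] == pytest.approx(4 * F1[1], rel=1e-10)
        # normalized magnitude is drive-invariant
        assert F2[2] == pytest.approx(F1[2], rel=1e-10)

    def test_normalized_magnitude_prefactor_invariant(self, small_solution):
        _, _, n1 = small_solution.dep_force(1e-24, 0.4, 0.9)
        _, _, n2 = small_solution.dep_force(7e-22, 0.4, 0.9)
        assert n1 == pytest.approx(n2, rel=1e-14)

    def test_local_minimum_at_gap_midline(self, small_solution):
        """|F_DEP*| dips at the midpoint between adjacent electrodes (the two
        edge contributions cancel in x there)."""
        y = 0.998
        x = np.array([0.46, 0.48, 0.5, 0.52, 0.54])
        _, _, Fn = small_solution.dep_force(1.0, x, np.full_like(x, y))
        assert Fn[2] == np.min(Fn)

    def test_decay_with_height(self, type_a, drive, gap):
        """Near the electrode edge the force at 30 um below the plane has
        decayed by >= 2 orders of magnitude relative to 2 um below (the
        near-edge force falls off as a steep power of the distance)."""
        sol = build_solution(type_a, drive, gap=gap, n_terms=2000)
        y2 = 1.0 - 2e-6 / type_a.H
        y30 = 1.0 - 30e-6 / type_a.H
        _, _, f2 = sol.dep_force(1.0, 0.25, y2)
        _, _, f30 = sol.dep_force(1.0, 0.25, y30)
        assert f2 >= 100 * f30

    def test_rejects_nonfinite_prefactor(self, small_solution):
        with pytest.raises(ValueError):
            small_solution.dep_force(np.inf, 0.5, 0.5)


class TestLaplaceResidual:
    def test_interior_residual_at_rounding_level(self, small_solution, drive,
                                                 rng):
        x = rng.uniform(0.05, 0.95, 25)
        y = rng.uniform(0.05, 0.99, 25)
        res = small_solution.laplace_residual(x, y)
        # term-wise exact cancellation; numerically only rounding survives
        assert np.max(np.abs(res)) < 1e-9 * drive.V_rms


class TestFieldGrid:
    def test_two_by_two_corners(self, small_solution, drive):
        grid = field_grid(small_solution, 1e-24, 2, 2)
        np.testing.assert_array_equal(grid.phi[0, :], 0.0)
        assert grid.phi.shape == (2, 2)

    def test_matches_pointwise_calls(self, small_solution):
        grid = field_grid(small_solution, 1e-24, 7, 9)
        X, Y = np.meshgrid(grid.x_star, grid.y_star)
        np.testing.assert_allclose(grid.phi,
                                   small_solution.potential(X, Y), rtol=1e-12)
        Ex, Ey = small_solution.electric_field(X, Y)
        np.testing.assert_allclose(grid.Ex, Ex, rtol=1e-12)
        np.testing.assert_allclose(grid.Ey, Ey, rtol=1e-12)
        Fx, Fy, Fn = small_solution.dep_force(1e-24, X[1:-1, 1:-1],
                                              Y[1:-1, 1:-1])
        np.testing.assert_allclose(grid.F_x[1:-1, 1:-1], Fx, rtol=1e-12)
        np.testing.assert_allclose(grid.F_norm[1:-1, 1:-1], Fn, rtol=1e-12)

    def test_boundary_sentinels(self, small_solution):
        grid = field_grid(small_solution, 1e-24, 6, 6)
        for arr in (grid.grad_E2_x, grid.grad_E2_y, grid.F_x, grid.F_y,
                    grid.F_norm):
            assert np.all(np.isnan(arr[0, :])) and np.all(np.isnan(arr[-1, :]))
            assert np.all(np.isnan(arr[:, 0])) and np.all(np.isnan(arr[:, -1]))
        assert np.all(np.isfinite(grid.phi))

    def test_grid_mirror_identity(self, type_a, drive, gap):
        sol = build_solution(type_a, drive, gap=gap, n_terms=2000)
        grid = field_grid(sol, 0.0, 101, 41)
        total = grid.phi + grid.phi[:, ::-1]
        np.testing.assert_allclose(
            total, drive.V_rms * grid.y_star[:, None] * np.ones((1, 101)),
            atol=2e-3 * drive.V_rms)

    def test_rejects_degenerate_lattice(self, small_solution):
        with pytest.raises(ValueError):
            field_grid(small_solution, 1.0, 1, 5)
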