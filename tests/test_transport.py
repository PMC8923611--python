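"""Semi-Lagrangian transport: departure points, interpolation, state and
adjoint solves, self-convergence."""

import numpy as np
import pytest

from diffeoreg import (
    Grid,
    ScalarField,
    VelocityField,
    periodic_interpolate,
    solve_adjoint,
    solve_state,
    trace_departure_points,
)
from diffeoreg.grid import FieldError, TWO_PI
from diffeoreg.transport import DeparturePoints, interpolate_values

from conftest import random_scalar, random_velocity


def observed_order(errors: list[float]) -> float:
    """Least-squares slope of log2(error) against log2(nt)."""
    x = np.arange(len(errors))
    return float(-np.polyfit(x, np.log2(errors), 1)[0])


class TestDeparturePoints:
    def test_zero_velocity_returns_nodes(self, grid32):
        dp = trace_departure_points(VelocityField.zeros(grid32), dt=0.1)
        assert np.abs(dp.coords - grid32.coords).max() <= 1e-14

    def test_constant_velocity_exact(self, grid32):
        c = 0.37
        v = VelocityField(
            grid32, np.stack([np.full(grid32.dims, c), np.zeros(grid32.dims)])
        )
        dp = trace_departure_points(v, dt=0.25)
        expected = np.mod(grid32.coords[0] - c * 0.25, TWO_PI)
        assert np.abs(dp.coords[0] - expected).max() <= 1e-12
        assert np.abs(dp.coords[1] - grid32.coords[1]).max() <= 1e-12

    def test_rotation_field_vs_fine_rk4_oracle(self):
        # Gaussian-windowed rigid rotation about the domain center: smooth,
        # periodic-friendly, analytically evaluable everywhere.
        grid = Grid((32, 32))
        omega, sigma = 1.0, 1.0

        def vel(p):
            dx, dy = p[0] - np.pi, p[1] - np.pi
            w = omega * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
            return np.stack([-w * dy, w * dx])

        v = VelocityField(grid, vel(grid.coords))
        dt = 0.1
        dp = trace_departure_points(v, dt)

        # oracle: 100-substep RK4 backward trace with the analytic velocity
        pos = grid.coords.copy()
        h = -dt / 100.0
        for _ in range(100):
            k1 = vel(pos)
            k2 = vel(pos + 0.5 * h * k1)
            k3 = vel(pos + 0.5 * h * k2)
            k4 = vel(pos + h * k3)
            pos = pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        err = np.abs(dp.coords - np.mod(pos, TWO_PI)).max()
        assert err <= 5e-4  # O(dt^3) + interpolation of v at the midpoint

    def test_huge_step_warns(self, grid16):
        v = VelocityField(grid16, np.full((2,) + grid16.dims, 10.0))
        with pytest.warns(UserWarning):
            trace_departure_points(v, dt=1.0)

    def test_nonpositive_dt_rejected(self, grid16):
        with pytest.raises(ValueError):
            trace_departure_points(VelocityField.zeros(grid16), dt=0.0)


class TestPeriodicInterpolate:
    @pytest.mark.parametrize("order", [1, 3])
    def test_exact_at_grid_nodes(self, grid32, order):
        f = random_scalar(grid32, 21)
        dp = DeparturePoints(grid32, grid32.coords.copy())
        out = periodic_interpolate(f, dp, order)
        assert np.abs(out.values - f.values).max() <= 1e-12

    @pytest.mark.parametrize("order", [1, 3])
    def test_constant_preserved_at_arbitrary_points(self, grid32, order):
        f = ScalarField(grid32, np.full(grid32.dims, 5.5))
        rng = np.random.default_rng(22)
        pts = rng.uniform(-5.0, 15.0, size=(2,) + grid32.dims)
        out = interpolate_values(f.values, pts, grid32, order)
        assert np.abs(out - 5.5).max() <= 1e-12

    def test_cubic_accuracy_on_sine(self, grid32):
        f = ScalarField.from_function(grid32, lambda x, y: np.sin(x))
        rng = np.random.default_rng(23)
        pts = rng.uniform(0.0, TWO_PI, size=(2, 100))
        vals = interpolate_values(f.values, pts.reshape(2, 10, 10), grid32, 3)
        assert np.abs(vals - np.sin(pts[0].reshape(10, 10))).max() <= 1e-4

    def test_linear_in_field(self, grid32):
        a = random_scalar(grid32, 24)
        b = random_scalar(grid32, 25)
        pts = np.random.default_rng(26).uniform(0, TWO_PI, (2,) + grid32.dims)
        lhs = interpolate_values(2.0 * a.values - 3.0 * b.values, pts, grid32, 3)
        rhs = 2.0 * interpolate_values(a.values, pts, grid32, 3) - 3.0 * interpolate_values(
            b.values, pts, grid32, 3
        )
        assert np.abs(lhs - rhs).max() <= 1e-11

    def test_nonfinite_coords_rejected(self, grid16):
        pts = grid16.coords.copy()
        pts[0, 0, 0] = np.nan
        with pytest.raises(FieldError):
            interpolate_values(np.zeros(grid16.dims), pts, grid16, 3)

    def test_bad_order_rejected(self, grid16):
        with pytest.raises(ValueError):
            interpolate_values(np.zeros(grid16.dims), grid16.coords, grid16, 2)


class TestSolveState:
    def test_zero_velocity_freezes_image(self, grid32):
        m0 = random_scalar(grid32, 31)
        traj = solve_state(m0, VelocityField.zeros(grid32), nt=4)
        for frame in traj.frames:
            assert np.abs(frame.values - m0.values).max() <= 1e-13

    def test_translation_of_sine(self, grid32):
        m0 = ScalarField.from_function(grid32, lambda x, y: np.sin(x))
        v = VelocityField(
            grid32, np.stack([np.ones(grid32.dims), np.zeros(grid32.dims)])
        )
        traj = solve_state(m0, v, nt=8)
        exact = np.sin(grid32.coords[0] - 1.0)
        assert np.abs(traj.final.values - exact).max() <= 1e-3

    def test_constants_preserved_exactly(self, grid32):
        m0 = ScalarField(grid32, np.full(grid32.dims, 0.8))
        v = random_velocity(grid32, 32, magnitude=0.5)
        traj = solve_state(m0, v, nt=8)
        for frame in traj.frames:
            assert np.abs(frame.values - 0.8).max() <= 1e-12

    def test_max_principle_with_linear_interpolation(self, grid32):
        m0 = random_scalar(grid32, 33)
        v = random_velocity(grid32, 34, magnitude=0.5)
        traj = solve_state(m0, v, nt=8, order=1)
        lo, hi = m0.values.min(), m0.values.max()
        for frame in traj.frames:
            assert frame.values.min() >= lo - 1e-12
            assert frame.values.max() <= hi + 1e-12

    def test_self_convergence_order(self):
        grid = Grid((128, 128))
        m0 = ScalarField.from_function(grid, lambda x, y: np.sin(x) + np.cos(y))
        v = random_velocity(grid, 7, magnitude=0.5)
        ref = solve_state(m0, v, nt=256).final.values
        errs = [
            np.abs(solve_state(m0, v, nt=nt).final.values - ref).max()
            for nt in (4, 8, 16)
        ]
        assert observed_order(errs) >= 1.8

    def test_grid_mismatch_rejected(self, grid16, grid32):
        with pytest.raises(FieldError):
            solve_state(ScalarField.zeros(grid16), VelocityField.zeros(grid32), nt=2)


class TestSolveAdjoint:
    def test_zero_velocity_freezes_multiplier(self, grid32):
        lam = random_scalar(grid32, 41)
        traj = solve_adjoint(lam, VelocityField.zeros(grid32), nt=4)
        for frame in traj.frames:
            assert np.abs(frame.values - lam.values).max() <= 1e-13

    def test_backward_translation_divergence_free(self, grid32):
        lam1 = ScalarField.from_function(grid32, lambda x, y: np.sin(x))
        v = VelocityField(
            grid32, np.stack([np.ones(grid32.dims), np.zeros(grid32.dims)])
        )
        traj = solve_adjoint(lam1, v, nt=8)
        exact = np.sin(grid32.coords[0] + 1.0)
        assert np.abs(traj.frames[0].values - exact).max() <= 1e-3
        assert np.abs(traj.final.values - lam1.values).max() == 0.0

    def test_mass_conservation_compressible(self, grid32):
        lam1 = ScalarField.from_function(
            grid32, lambda x, y: 1.0 + 0.3 * np.cos(y) + 0.2 * np.sin(x)
        )
        v = random_velocity(grid32, 42, magnitude=0.5, max_mode=2)
        traj = solve_adjoint(lam1, v, nt=16)
        total0 = traj.frames[0].values.sum()
        total1 = traj.final.values.sum()
        assert abs(total0 - total1) / abs(total1) <= 1e-2

    def test_translation_3d(self):
        # the same machinery runs unchanged on small 3D volumes
        g = Grid((16, 16, 16))
        m0 = ScalarField.from_function(g, lambda x, y, z: np.sin(x) + 0.5 * np.cos(z))
        v = VelocityField(
            g, np.stack([np.full(g.dims, 0.5), np.zeros(g.dims), np.zeros(g.dims)])
        )
        final = solve_state(m0, v, nt=8).final
        exact = np.sin(g.coords[0] - 0.5) + 0.5 * np.cos(g.coords[2])
        assert np.abs(final.values - exact).max() <= 5e-3

    def test_self_convergence_order(self):
        grid = Grid((128, 128))
        lam1 = ScalarField.from_function(grid, lambda x, y: np.sin(x) + np.cos(y))
        v = random_velocity(grid, 7, magnitude=0.5)
        ref = solve_adjoint(lam1, v, nt=256).frames[0].values
        errs = [
            np.abs(solve_adjoint(lam1, v, nt=nt).frames[0].values - ref).max()
            for nt in (4, 8, 16)
        ]
        assert observed_order(errs) >= 1.8
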