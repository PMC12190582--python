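"""Channel-flow solver versus closed forms: Poiseuille, forced flow, mass."""

import numpy as np
import pytest

from defcytosim.config import ChannelGeometry, to_si
from defcytosim.errors import ResolutionError, TimeStepError
from defcytosim.fluid import (
    ProjectionSolver,
    build_grid,
    flow_diagnostics,
    poiseuille_profile,
    set_inlet_flow,
    step_fluid,
)
from defcytosim.verify import poiseuille_l2_error

RHO = 1000.0


def straight_channel(n_across=16, length_um=60.0):
    geom = ChannelGeometry(channel_length=length_um, reservoir_length=0.0,
                           reservoir_width=20.0)
    h = geom.width_m / n_across
    return geom, build_grid(geom, h)


def run_to_steady(solver, grid, state, tol, max_steps=6000):
    for _ in range(max_steps):
        new = solver.step(state)
        delta = np.abs(new.u - state.u).max()
        state = new
        if delta < tol:
            break
    return state


class TestGrid:
    def test_channel_row_count(self):
        geom = ChannelGeometry(channel_length=100.0, reservoir_length=0.0,
                               reservoir_width=20.0)
        grid = build_grid(geom, 1e-6)
        assert len(grid.channel_rows) == 20
        assert grid.fluid.all()

    def test_reservoir_constriction_mask(self):
        geom = ChannelGeometry(channel_length=100.0, reservoir_length=60.0,
                               reservoir_width=60.0)
        grid = build_grid(geom, 1e-6)
        # reservoir column fully fluid; channel column only 20 rows
        assert grid.fluid[:, 5].all()
        mid = grid.nx // 2
        assert grid.fluid[:, mid].sum() == 20
        assert not grid.fluid[0, mid]

    def test_too_coarse_spacing_rejected(self):
        geom = ChannelGeometry()
        with pytest.raises(ResolutionError):
            build_grid(geom, 2e-6)  # only 10 cells across


class TestPoiseuilleProfile:
    def test_centerline_and_walls(self):
        assert poiseuille_profile(0.0, 4.1667, 20e-6) == pytest.approx(6.25, rel=1e-4)
        assert poiseuille_profile(10e-6, 1.0, 20e-6) == 0.0
        assert poiseuille_profile(-10e-6, 1.0, 20e-6) == 0.0

    def test_mean_is_u_mean(self):
        y = (np.arange(2000) + 0.5) / 2000 * 20e-6 - 10e-6
        assert poiseuille_profile(y, 1.0, 20e-6).mean() == pytest.approx(1.0, abs=1e-4)

    def test_outside_channel_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_profile(11e-6, 1.0, 20e-6)


class TestSteadyChannelFlow:
    def test_matches_parabola_within_one_percent(self):
        assert poiseuille_l2_error(n_across=20) <= 0.01

    def test_error_decreases_with_refinement(self):
        """Observed convergence order >= 1.5 on a quartic forced profile.

        The parabolic Poiseuille solution is exact on this grid (quadratic
        wall stencil), so the order is measured on a quartic steady profile
        u(y) = c y^2 (W - y)^2 driven by the matching body force, which has
        a genuine O(h^2) truncation error.
        """
        errs = {}
        for n in (16, 32):
            errs[n] = self._quartic_forced_error(n)
        order = np.log2(errs[16] / errs[32])
        assert order >= 1.5

    @staticmethod
    def _quartic_forced_error(n_across):
        geom, grid = straight_channel(n_across=n_across, length_um=40.0)
        W, eta = geom.width_m, 1e-3
        c = 4e22  # 1/(m^3 s): peak velocity c W^4/16 ~ 1 m/s
        yc = (np.arange(grid.ny) + 0.5) * grid.h
        target = c * yc ** 2 * (W - yc) ** 2
        force = -eta * c * (2 * W * W - 12 * W * yc + 12 * yc ** 2)
        grid.inlet_u = target
        grid.u_mean = target.mean()
        u_max = c * W ** 4 / 16
        solver = ProjectionSolver(grid, RHO, eta, 0.4 * grid.h / u_max)
        f_u = np.tile(force[:, None], (1, grid.nx + 1))
        st = grid.zero_state()
        prev = st
        for _ in range(8000):
            st = solver.step(prev, f_u=f_u)
            if np.abs(st.u - prev.u).max() < 1e-8 * u_max:
                break
            prev = st
        num = st.u[:, grid.nx // 2]
        return np.linalg.norm(num - target) / np.linalg.norm(target)

    def test_rest_state_stays_at_rest(self):
        geom, grid = straight_channel()
        set_inlet_flow(grid, 0.0)
        solver = ProjectionSolver(grid, RHO, 1e-3, 1e-7)
        st = grid.zero_state()
        for _ in range(5):
            st = solver.step(st)
        assert np.abs(st.u).max() == 0.0
        assert np.abs(st.v).max() == 0.0

    def test_uniform_body_force_gives_forced_parabola(self):
        """Uniform streamwise body force with the matching inlet profile keeps
        the analytic forced-channel solution u(y) = g y (W - y) / (2 eta)."""
        geom, grid = straight_channel(n_across=16, length_um=40.0)
        W, eta = geom.width_m, 1e-3
        g = 2e8  # N/m^3
        u_max = g * W * W / (8 * eta)
        yc = (np.arange(grid.ny) + 0.5) * grid.h
        prof = g * yc * (W - yc) / (2 * eta)
        grid.inlet_u = prof
        grid.u_mean = prof.mean()
        dt = 0.4 * grid.h / u_max
        solver = ProjectionSolver(grid, RHO, eta, dt)
        f_u = np.full((grid.ny, grid.nx + 1), g)
        st = grid.zero_state()
        prev = st
        for _ in range(4000):
            st = solver.step(prev, f_u=f_u)
            if np.abs(st.u - prev.u).max() < 1e-7 * u_max:
                break
            prev = st
        num = st.u[:, grid.nx // 2]
        assert np.linalg.norm(num - prof) / np.linalg.norm(prof) <= 0.01

    def test_mass_conservation_and_divergence(self):
        geom, grid = straight_channel()
        U = 0.8333
        set_inlet_flow(grid, U)
        solver = ProjectionSolver(grid, RHO, 1e-3, 0.4 * grid.h / (1.5 * U))
        st = run_to_steady(solver, grid, grid.zero_state(), 1e-7 * U)
        d = flow_diagnostics(st, grid)
        assert abs(d["inflow"] - d["outflow"]) / d["inflow"] <= 1e-3
        assert d["max_div"] <= grid.div_tol
        assert d["V1"] == pytest.approx(U, rel=0.01)

    def test_stokes_linearity(self):
        """At Re << 1, halving the inlet velocity halves the steady field."""
        geom, grid = straight_channel(n_across=16, length_um=40.0)
        fields = []
        for U in (2e-4, 1e-4):
            set_inlet_flow(grid, U)
            solver = ProjectionSolver(grid, RHO, 1e-3, 1e-7)
            st = run_to_steady(solver, grid, grid.zero_state(), 1e-9 * U)
            fields.append(st.u.copy())
        assert np.allclose(fields[0], 2 * fields[1], rtol=1e-4,
                           atol=1e-9 * fields[0].max())

    def test_cfl_violation_raises(self):
        geom, grid = straight_channel()
        U = 1.0
        set_inlet_flow(grid, U)
        solver = ProjectionSolver(grid, RHO, 1e-3, 10 * grid.h / U)
        with pytest.raises(TimeStepError):
            solver.step(grid.zero_state())

    def test_step_fluid_wrapper(self):
        from defcytosim.config import FluidProps
        geom, grid = straight_channel(length_um=40.0)
        U = 0.1
        set_inlet_flow(grid, U)
        st = step_fluid(grid.zero_state(), grid, FluidProps(viscosity=1.0),
                        0.2 * grid.h / U)
        assert st.t > 0
        assert np.isfinite(st.u).all()
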