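"""Immersed-boundary transfer operators and short coupled runs."""

import numpy as np
import pytest

from defcytosim.config import ChannelGeometry, SimConfig
from defcytosim.coupling import (
    TransitEngine,
    interpolate_velocity,
    new_state,
    run_transit,
    spread_forces,
)
from defcytosim.errors import NodeEscapeError
from defcytosim.fluid import build_grid, set_inlet_flow
from defcytosim.solid import build_disk_mesh


@pytest.fixture()
def small_grid():
    geom = ChannelGeometry(channel_length=60.0, reservoir_length=0.0,
                           reservoir_width=20.0)
    return build_grid(geom, geom.width_m / 16)


@pytest.fixture()
def centered_mesh(small_grid):
    return build_disk_mesh(10e-6, 1.2e-6,
                           center=(small_grid.Lx / 2, small_grid.Ly / 2))


class TestSpreading:
    def test_zero_forces_zero_field(self, small_grid, centered_mesh):
        f_u, f_v = spread_forces(np.zeros_like(centered_mesh.cur_nodes),
                                 centered_mesh, small_grid)
        assert np.abs(f_u).max() == 0.0
        assert np.abs(f_v).max() == 0.0

    def test_partition_of_unity_single_node(self, small_grid, centered_mesh):
        forces = np.zeros_like(centered_mesh.cur_nodes)
        forces[0] = (1.0, 0.0)
        f_u, f_v = spread_forces(forces, centered_mesh, small_grid)
        h = small_grid.h
        assert f_u.sum() * h * h == pytest.approx(1.0, rel=1e-12)
        assert np.abs(f_v).max() == 0.0
        # support is the 4x4 kernel footprint
        assert (np.abs(f_u) > 0).sum() <= 16

    def test_total_force_conserved(self, small_grid, centered_mesh):
        rng = np.random.default_rng(5)
        forces = rng.normal(0.0, 1e-9, centered_mesh.cur_nodes.shape)
        f_u, f_v = spread_forces(forces, centered_mesh, small_grid)
        h2 = small_grid.h ** 2
        assert f_u.sum() * h2 == pytest.approx(forces[:, 0].sum(), rel=1e-12)
        assert f_v.sum() * h2 == pytest.approx(forces[:, 1].sum(), rel=1e-12)

    def test_node_outside_domain_raises(self, small_grid, centered_mesh):
        centered_mesh.cur_nodes[3] = (small_grid.Lx + 1e-6, small_grid.Ly / 2)
        with pytest.raises(NodeEscapeError):
            spread_forces(np.ones_like(centered_mesh.cur_nodes),
                          centered_mesh, small_grid)


class TestInterpolation:
    def test_constant_field_reproduced(self, small_grid, centered_mesh):
        st = small_grid.zero_state()
        st.u[:] = 0.37
        st.v[:] = -0.11
        vel = interpolate_velocity(st, centered_mesh, small_grid)
        assert vel[:, 0] == pytest.approx(0.37, rel=1e-12)
        assert vel[:, 1] == pytest.approx(-0.11, rel=1e-12)

    def test_zero_field_zero_velocities(self, small_grid, centered_mesh):
        vel = interpolate_velocity(small_grid.zero_state(), centered_mesh,
                                   small_grid)
        assert np.abs(vel).max() == 0.0

    def test_linear_field_exact(self, small_grid, centered_mesh):
        """The 4-point kernel has vanishing first moments, so linear fields
        interpolate to round-off (the refinement limit of the O(h^2) bound)."""
        g = small_grid
        st = g.zero_state()
        a, b, c = 0.2, 3e3, -1e3
        xf = np.arange(g.nx + 1) * g.h
        yf = (np.arange(g.ny) + 0.5) * g.h
        st.u[:] = a + b * xf[None, :] + c * yf[:, None]
        vel = interpolate_velocity(st, centered_mesh, g)
        X = centered_mesh.cur_nodes
        expected = a + b * X[:, 0] + c * X[:, 1]
        assert vel[:, 0] == pytest.approx(expected, rel=1e-10)


class TestCoupledCycle:
    def test_quiescent_equilibrium(self):
        cfg = SimConfig.from_dict({
            "geometry": {"channel_length": 60.0, "reservoir_length": 0.0,
                         "reservoir_width": 20.0},
            "fluid": {"flow_rate": 0.0},
            "cell": {"diameter": 10.0, "initial_center": [30.0, 10.0]},
            "solver": {"grid_spacing": 1.25, "max_time": 1.0},
        })
        eng = TransitEngine(cfg)
        x0 = eng.mesh.cur_nodes.copy()
        for _ in range(5):
            eng.advance()
        assert np.abs(eng.mesh.cur_nodes - x0).max() < 1e-15
        assert eng.state.t > 0

    def test_momentum_transfer_equals_nodal_total(self):
        """Newton's third law at the discrete level during a real step."""
        from defcytosim.solid import elastic_forces
        cfg = _tiny_transit_config()
        eng = TransitEngine(cfg)
        for _ in range(50):
            eng.advance()
        f = elastic_forces(eng.mesh, eng.mat)
        f_u, f_v = spread_forces(f, eng.mesh, eng.grid)
        h2 = eng.grid.h ** 2
        scale = np.abs(f).sum() + 1e-300
        assert abs(f_u.sum() * h2 - f[:, 0].sum()) / scale < 1e-12
        assert abs(f_v.sum() * h2 - f[:, 1].sum()) / scale < 1e-12

    def test_bit_identical_reruns(self):
        tr1 = run_transit(_tiny_transit_config())
        tr2 = run_transit(_tiny_transit_config())
        assert np.array_equal(tr1.DI, tr2.DI)
        assert np.array_equal(tr1.centroid, tr2.centroid)
        assert np.array_equal(tr1.tau, tr2.tau)

    def test_advance_function_wraps_engine(self):
        cfg = _tiny_transit_config()
        from defcytosim.coupling import advance
        st = new_state(cfg)
        t0 = st.t
        st = advance(st, cfg)
        assert st.t > t0 and st.step == 1


def _tiny_transit_config(**cell):
    cell_d = {"diameter": 10.0}
    cell_d.update(cell)
    return SimConfig.from_dict({
        "geometry": {"channel_length": 60.0, "reservoir_length": 30.0,
                     "reservoir_width": 40.0},
        "fluid": {"flow_rate": 20.0, "viscosity": 1.0},
        "cell": cell_d,
        "solver": {"grid_spacing": 1.25, "output_stride": 50,
                   "max_time": 0.02},
    })


class TestTransit:
    def test_rest_flow_cell_stays_put(self):
        cfg = SimConfig.from_dict({
            "geometry": {"channel_length": 60.0, "reservoir_length": 30.0,
                         "reservoir_width": 40.0},
            "fluid": {"flow_rate": 0.0},
            "solver": {"grid_spacing": 1.25, "max_time": 0.005,
                       "output_stride": 20},
        })
        with pytest.warns(UserWarning, match="max_time"):
            tr = run_transit(cfg)
        assert not tr.exited
        assert np.abs(tr.centroid[-1] - tr.centroid[0]).max() < 1e-12
        assert tr.DI == pytest.approx(1.0, abs=1e-9)

    def test_di_never_below_one(self):
        tr = run_transit(_tiny_transit_config())
        assert (tr.DI >= 1.0 - 1e-12).all()
        assert (np.diff(tr.times) > 0).all()

    def test_stiffness_reduces_deformation(self):
        """Monotone rigid limit: DI - 1 falls as G grows (fixed dashpot)."""
        dis = []
        for E in (1500.0, 15000.0, 150000.0):
            cfg = _full_short_transit(E)
            dis.append(run_transit(cfg).steady_value("DI") - 1.0)
        assert dis[0] > dis[1] > dis[2] > 0


def _full_short_transit(E):
    return SimConfig.from_dict({
        "geometry": {"channel_length": 60.0, "reservoir_length": 30.0,
                     "reservoir_width": 40.0},
        "fluid": {"flow_rate": 20.0, "viscosity": 1.0},
        "cell": {"young_modulus": E, "cell_viscosity": 20.0},
        "solver": {"grid_spacing": 1.25, "output_stride": 50},
    })
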