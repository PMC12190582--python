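"""Immersed-boundary coupling of the fluid grid and the Lagrangian cell.

One explicit coupling cycle per time step:

1. assemble nodal elastic forces on the cell mesh,
2. spread them to the staggered grid with the 4-point regularized delta
   kernel (total spread force equals total nodal force to round-off),
3. advance the fluid one projection step, with the cell's Kelvin--Voigt
   dashpot realized as an elevated viscosity (eta_fluid + eta_c) inside
   the cell's current contour, treated implicitly,
4. interpolate grid velocities back to the nodes with the adjoint kernel
   and move the nodes with them (no-slip of the immersed boundary).

The solid is massless and the pipeline contains no randomness: identical
configs give bit-identical trajectories.

The time step is auto-selected from the advective CFL bound and an
elastic-stiffness bound dt <= C ds sqrt(rho / kappa) (ds = solid mesh
edge), the standard wave-speed heuristic for explicit immersed elastic
bodies; C is a frozen package constant validated by the rigid-limit and
conservation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely

from . import solid as solid_mod
from .config import SimConfig
from .errors import NodeEscapeError, TimeStepError, TransitTimeoutWarning
from .fluid import FluidGrid, FluidState, ProjectionSolver, build_grid, set_inlet_flow
from . import metrics as metrics_mod

__all__ = [
    "SimulationState",
    "Trajectory",
    "spread_forces",
    "interpolate_velocity",
    "advance",
    "run_transit",
    "TransitEngine",
]

#: Elastic time-step safety factor in dt <= C * ds * sqrt(rho/kappa).
ELASTIC_DT_SAFETY = 0.5

#: Steps between refreshes of the cell-interior viscosity field (the cell
#: moves a small fraction of a grid cell per step, so the indicator lags
#: by well under one spacing).
VISC_REFRESH_STRIDE = 20

#: Blockage allowance in the advective-CFL velocity estimate.
_CFL_BLOCKAGE_MARGIN = 1.3


def _phi(r: np.ndarray) -> np.ndarray:
    """Peskin 4-point regularized delta (support |r| < 2, sums to 1)."""
    a = np.abs(r)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m1] = (3.0 - 2.0 * a[m1] + np.sqrt(1.0 + 4.0 * a[m1] - 4.0 * a[m1] ** 2)) / 8.0
    out[m2] = (5.0 - 2.0 * a[m2] - np.sqrt(-7.0 + 12.0 * a[m2] - 4.0 * a[m2] ** 2)) / 8.0
    return out


def _stencil(coord: np.ndarray, offset: float, h: float, n_max: int):
    """4-point stencil indices and weights along one axis.

    ``offset`` is the grid-line coordinate of index 0 (0 for face positions
    x_i = i h, 0.5 h for centers).  Raises NodeEscapeError if the support
    leaves [0, n_max].
    """
    s = (coord - offset) / h
    i0 = np.floor(s).astype(np.int64) - 1
    idx = i0[:, None] + np.arange(4)[None, :]
    if idx.min() < 0 or idx.max() > n_max:
        bad = int(np.nonzero((idx.min(axis=1) < 0) | (idx.max(axis=1) > n_max))[0][0])
        raise NodeEscapeError(bad)
    w = _phi(s[:, None] - idx)
    return idx, w


def spread_forces(node_forces: np.ndarray, mesh: solid_mod.CellMesh,
                  grid: FluidGrid) -> tuple[np.ndarray, np.ndarray]:
    """Spread nodal forces (N/m per node) to staggered body-force fields (N/m^3).

    Discrete realization of the two-way traction transfer: the fluid sees
    exactly the (negated elsewhere) load the solid carries; the sum of the
    spread field times h^2 equals the total nodal force to round-off.
    """
    X = mesh.cur_nodes
    h = grid.h
    f_u = np.zeros((grid.ny, grid.nx + 1))
    f_v = np.zeros((grid.ny + 1, grid.nx))
    # u faces: x = i h, y = (j + 1/2) h
    ix, wx = _stencil(X[:, 0], 0.0, h, grid.nx)
    jy, wy = _stencil(X[:, 1], 0.5 * h, h, grid.ny - 1)
    w = wy[:, :, None] * wx[:, None, :] / (h * h)
    np.add.at(f_u, (jy[:, :, None], ix[:, None, :]),
              w * node_forces[:, 0, None, None])
    # v faces: x = (i + 1/2) h, y = j h
    ix2, wx2 = _stencil(X[:, 0], 0.5 * h, h, grid.nx - 1)
    jy2, wy2 = _stencil(X[:, 1], 0.0, h, grid.ny)
    w2 = wy2[:, :, None] * wx2[:, None, :] / (h * h)
    np.add.at(f_v, (jy2[:, :, None], ix2[:, None, :]),
              w2 * node_forces[:, 1, None, None])
    return f_u, f_v


def interpolate_velocity(state: FluidState, mesh: solid_mod.CellMesh,
                         grid: FluidGrid) -> np.ndarray:
    """Node velocities by the adjoint kernel; exact for constant fields."""
    X = mesh.cur_nodes
    h = grid.h
    ix, wx = _stencil(X[:, 0], 0.0, h, grid.nx)
    jy, wy = _stencil(X[:, 1], 0.5 * h, h, grid.ny - 1)
    w = wy[:, :, None] * wx[:, None, :]
    un = (w * state.u[jy[:, :, None], ix[:, None, :]]).sum(axis=(1, 2))
    ix2, wx2 = _stencil(X[:, 0], 0.5 * h, h, grid.nx - 1)
    jy2, wy2 = _stencil(X[:, 1], 0.0, h, grid.ny)
    w2 = wy2[:, :, None] * wx2[:, None, :]
    vn = (w2 * state.v[jy2[:, :, None], ix2[:, None, :]]).sum(axis=(1, 2))
    return np.column_stack([un, vn])


def _cell_viscosity_field(mesh: solid_mod.CellMesh, grid: FluidGrid,
                          eta0: float, eta_c: float) -> np.ndarray:
    """eta0 everywhere, eta0 + eta_c at cell centers inside the contour."""
    eta = np.full((grid.ny, grid.nx), eta0)
    if eta_c <= 0:
        return eta
    poly = shapely.Polygon(mesh.contour)
    xmin, ymin, xmax, ymax = poly.bounds
    h = grid.h
    i0 = max(0, int(xmin / h) - 1)
    i1 = min(grid.nx, int(xmax / h) + 2)
    j0 = max(0, int(ymin / h) - 1)
    j1 = min(grid.ny, int(ymax / h) + 2)
    xs = (np.arange(i0, i1) + 0.5) * h
    ys = (np.arange(j0, j1) + 0.5) * h
    XX, YY = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(XX.shape)
    eta[j0:j1, i0:i1][inside] += eta_c
    return eta


# ---------------------------------------------------------------------------
# State and trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    fluid: FluidState
    cell: solid_mod.CellMesh
    t: float = 0.0
    step: int = 0
    _engine: Optional["TransitEngine"] = field(default=None, repr=False)


@dataclass
class Trajectory:
    """Sampled time series of one cell transit (SI units)."""

    times: np.ndarray            # (n,)
    centroid: np.ndarray         # (n, 2)
    V0: np.ndarray               # (n,) centroid velocity, streamwise
    DI: np.ndarray               # (n,)
    area: np.ndarray             # (n,) m^2
    tau: np.ndarray              # (n,) Pa
    V1: np.ndarray               # (n,) m/s
    contours: list               # list of (B, 2) arrays
    config: SimConfig
    exited: bool
    dt: float

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.times,
            "x": self.centroid[:, 0],
            "y": self.centroid[:, 1],
            "V0": self.V0,
            "V1": self.V1,
            "DI": self.DI,
            "area": self.area,
            "tau": self.tau,
        })

    def _steady_mask(self) -> np.ndarray:
        g = self.config.geometry
        x0 = g.reservoir_length_m
        L = g.channel_length_m
        x = self.centroid[:, 0]
        return (x >= x0 + 0.25 * L) & (x <= x0 + 0.75 * L)

    def steady_value(self, name: str) -> float:
        """Median of a recorded series over the mid-channel window."""
        mask = self._steady_mask()
        if not mask.any():
            return float("nan")
        return float(np.median(getattr(self, name)[mask]))

    @property
    def steady_DI(self) -> float:
        return self.steady_value("DI")

    @property
    def area_drift(self) -> float:
        """Max relative area deviation from the initial sample."""
        if len(self.area) == 0:
            return 0.0
        a0 = self.area[0]
        return float(np.abs(self.area / a0 - 1.0).max())


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class TransitEngine:
    """Owns grid, mesh, solver caches and the coupling cycle for one run."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        g = config.geometry
        h = config.grid_spacing_si
        self.grid = build_grid(g, h)
        set_inlet_flow(self.grid, config.mean_velocity)
        self.mat = solid_mod.MaterialParams(
            G=config.cell.shear_modulus,
            eta_c=config.cell.cell_viscosity_si,
            tau_r=config.cell.relaxation_time_si,
        )
        edge = config.mesh_edge_si
        self.mesh = solid_mod.build_disk_mesh(
            config.cell.diameter_si, edge, center=config.release_center
        )
        self.rho = config.fluid.density
        self.eta0 = config.fluid.viscosity_si
        self.dt = self._auto_dt()
        self.solver = ProjectionSolver(self.grid, self.rho, self.eta0, self.dt)
        self._refresh_viscosity()
        self.state = SimulationState(
            fluid=self._initial_fluid(), cell=self.mesh, t=0.0, step=0,
            _engine=self,
        )

    # ---- setup helpers ----------------------------------------------------
    def _auto_dt(self) -> float:
        cfg = self.config
        ts = cfg.solver.time_step
        if not isinstance(ts, str):
            return float(ts)
        h = self.grid.h
        W = cfg.geometry.width_m
        a = cfg.cell.diameter_si
        u_ref = 1.5 * cfg.mean_velocity * max(_CFL_BLOCKAGE_MARGIN,
                                              W / max(W - a, 0.2 * W))
        dt_cfl = h / max(u_ref, 1e-12)
        ds = cfg.mesh_edge_si
        dt_el = ELASTIC_DT_SAFETY * ds * np.sqrt(self.rho / self.mat.kappa)
        return cfg.solver.cfl_limit * min(dt_cfl, dt_el / cfg.solver.cfl_limit)

    def _initial_fluid(self) -> FluidState:
        """Section-wise developed profile; the projection cleans it up."""
        g = self.grid
        st = g.zero_state()
        yc = (np.arange(g.ny) + 0.5) * g.h
        mid = g.Ly / 2.0
        for i in range(g.nx + 1):
            col = min(i, g.nx - 1)
            rows = g.fluid[:, col]
            if i > 0 and i < g.nx:
                rows = g.fluid[:, i - 1] & g.fluid[:, i]
            opening = rows.sum() * g.h
            if opening <= 0:
                continue
            u_loc = g.u_mean * g.width / opening
            ylo = yc[rows].min() - 0.5 * g.h
            yc_mid = ylo + opening / 2.0
            prof = 1.5 * u_loc * (1.0 - (2.0 * (yc - yc_mid) / opening) ** 2)
            st.u[rows, i] = prof[rows]
        st.u[:, 0] = g.inlet_u
        return st

    def _refresh_viscosity(self) -> None:
        eta = _cell_viscosity_field(self.mesh, self.grid, self.eta0,
                                    self.mat.eta_c)
        self.solver.set_viscosity(eta)

    # ---- one coupling cycle ----------------------------------------------
    def advance(self) -> SimulationState:
        st = self.state
        forces = solid_mod.elastic_forces(self.mesh, self.mat)
        f_u, f_v = spread_forces(forces, self.mesh, self.grid)
        if self.mat.eta_c > 0 and st.step % VISC_REFRESH_STRIDE == 0:
            self._refresh_viscosity()
        while True:
            try:
                new_fluid = self.solver.step(st.fluid, f_u=f_u, f_v=f_v)
                break
            except TimeStepError:
                # deterministic fallback: halve dt and refactorize
                self.dt /= 2.0
                self.solver.dt = self.dt
                self.solver.set_viscosity(self.solver.eta_cc)
        vel = interpolate_velocity(new_fluid, self.mesh, self.grid)
        self.mesh.cur_nodes = self.mesh.cur_nodes + self.dt * vel
        self.mesh.node_velocities = vel
        st.fluid = new_fluid
        st.t += self.dt
        st.step += 1
        return st

    # ---- measurement ------------------------------------------------------
    def sample(self):
        from .fluid import flow_diagnostics
        mesh = self.mesh
        cfg = self.config
        contour = mesh.contour.copy()
        sm = metrics_mod.deformation_index(contour)
        w = mesh.node_weights
        v0 = float((w @ mesh.node_velocities[:, 0]) / w.sum())
        diag = flow_diagnostics(self.state.fluid, self.grid)
        V1 = diag["V1"]
        gamma = metrics_mod.shear_rate(V1, v0, cfg.cell.diameter_si)
        tau = metrics_mod.shear_stress(gamma, cfg.fluid.viscosity_si)
        return {
            "t": self.state.t,
            "centroid": mesh.centroid(),
            "V0": v0,
            "V1": V1,
            "DI": sm.DI,
            "area": solid_mod.cell_area(mesh),
            "tau": tau,
            "contour": contour,
        }


def advance(state: SimulationState, config: SimConfig) -> SimulationState:
    """One coupling cycle on an existing state (engine cached on the state)."""
    if state._engine is None:
        eng = TransitEngine(config)
        eng.state = state
        eng.mesh = state.cell
        state._engine = eng
    return state._engine.advance()


def new_state(config: SimConfig) -> SimulationState:
    """Fresh simulation state (fluid initialized, cell at the release point)."""
    return TransitEngine(config).state


def run_transit(config: SimConfig,
                engine: Optional[TransitEngine] = None) -> Trajectory:
    """Simulate one cell transit and record the trajectory.

    Runs from the release point until the cell centroid passes the exit
    station (past the channel outlet, into the outlet reservoir) or
    ``max_time`` elapses (then a TransitTimeoutWarning is issued and the
    partial trajectory returned).  Pass a prebuilt ``engine`` to keep
    access to the final fields afterwards (snapshot export).
    """
    eng = TransitEngine(config) if engine is None else engine
    config = eng.config
    g = config.geometry
    grid = eng.grid
    if g.has_reservoirs:
        x_stop = grid.x_channel[1] + min(0.7 * g.reservoir_length_m,
                                         2.0 * config.cell.diameter_si)
    else:
        x_stop = grid.Lx - 0.75 * config.cell.diameter_si
    x_stop = min(x_stop, grid.Lx - 0.6 * config.cell.diameter_si)
    mt = config.solver.max_time
    if mt is None:
        u_res = config.mean_velocity * g.width_m / grid.Ly
        max_time = 8.0 * grid.Lx / max(u_res, 1e-12)
    else:
        max_time = mt * 1e-3
    stride = config.solver.output_stride
    h = grid.h
    samples = [eng.sample()]
    exited = False
    while eng.state.t < max_time:
        eng.advance()
        # leading-node guard every step: a strongly elongated cell's nose
        # must never reach the kernel-support margin at the domain end
        nose_out = eng.mesh.cur_nodes[:, 0].max() >= grid.Lx - 3.0 * h
        if eng.state.step % stride == 0 or nose_out:
            s = eng.sample()
            samples.append(s)
            if s["centroid"][0] >= x_stop or nose_out:
                exited = True
                break
    if not exited:
        warnings.warn(
            f"max_time {max_time:g} s reached before the cell passed "
            f"x = {x_stop:g} m; returning partial trajectory",
            TransitTimeoutWarning,
        )
    return Trajectory(
        times=np.array([s["t"] for s in samples]),
        centroid=np.array([s["centroid"] for s in samples]),
        V0=np.array([s["V0"] for s in samples]),
        DI=np.array([s["DI"] for s in samples]),
        area=np.array([s["area"] for s in samples]),
        tau=np.array([s["tau"] for s in samples]),
        V1=np.array([s["V1"] for s in samples]),
        contours=[s["contour"] for s in samples],
        config=config,
        exited=exited,
        dt=eng.dt,
    )
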