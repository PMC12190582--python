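"""Built-in verification oracles.

Self-contained checks against closed forms, runnable via
``defcytosim verify``: plane-Poiseuille flow, Kelvin--Voigt creep
through the actual force assembly, force-spreading conservation, and a
(slow) rigid-limit transit.  Test modules reuse these helpers.
"""

from __future__ import annotations

import numpy as np

from .config import ChannelGeometry, SimConfig, flowrate_to_mean_velocity, to_si
from .coupling import run_transit, spread_forces
from .fluid import ProjectionSolver, build_grid, poiseuille_profile, set_inlet_flow
from .solid import CellMesh, MaterialParams, build_disk_mesh, elastic_forces, kv_step_response

__all__ = [
    "poiseuille_l2_error",
    "kv_creep_via_element",
    "spreading_conservation_error",
    "run_verification",
]


def poiseuille_l2_error(n_across: int = 16, length_um: float = 60.0,
                        flow_rate: float = 20.0, viscosity_mpas: float = 1.0,
                        max_steps: int = 6000) -> float:
    """Relative L2 error of the steady no-cell channel flow vs. the parabola."""
    geom = ChannelGeometry(channel_length=length_um, reservoir_length=0.0,
                           reservoir_width=20.0)
    h = geom.width_m / n_across
    grid = build_grid(geom, h)
    U = flowrate_to_mean_velocity(to_si(flow_rate, "uL/min"), geom)
    set_inlet_flow(grid, U)
    rho, eta = 1000.0, to_si(viscosity_mpas, "mPa.s")
    dt = 0.5 * h / (1.5 * U)
    solver = ProjectionSolver(grid, rho, eta, dt)
    st = grid.zero_state()
    for _ in range(max_steps):
        st2 = solver.step(st)
        if np.abs(st2.u - st.u).max() < 1e-8 * U:
            st = st2
            break
        st = st2
    yc = (np.arange(grid.ny) + 0.5) * h - grid.Ly / 2
    ana = poiseuille_profile(yc, U, geom.width_m)
    num = st.u[:, grid.nx // 2]
    return float(np.linalg.norm(num - ana) / np.linalg.norm(ana))


def _single_shear_element() -> tuple[CellMesh, float]:
    """Unit right-triangle element for constitutive-level checks."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    mesh = CellMesh(
        ref_nodes=nodes, cur_nodes=nodes.copy(),
        node_velocities=np.zeros_like(nodes),
        triangles=np.array([[0, 1, 2]]), ref_areas=np.array([0.5]),
        boundary=np.array([0, 1, 2]), diameter=1.0,
    )
    return mesh, 0.5


def element_shear_stress(gamma: float, mat: MaterialParams) -> float:
    """Cauchy shear stress of the element under simple shear, recovered
    from the assembled nodal forces (not from the constitutive formula)."""
    mesh, area = _single_shear_element()
    F = np.array([[1.0, gamma], [0.0, 1.0]])
    mesh.cur_nodes = mesh.ref_nodes @ F.T
    f = elastic_forces(mesh, mat)
    H = np.column_stack([f[1], f[2]])          # forces on local nodes 1, 2
    dm = np.column_stack([mesh.ref_nodes[1] - mesh.ref_nodes[0],
                          mesh.ref_nodes[2] - mesh.ref_nodes[0]])
    P = -(1.0 / area) * H @ dm.T               # first Piola stress
    J = np.linalg.det(F)
    sigma = P @ F.T / J
    return float(sigma[0, 1])


def kv_creep_via_element(sigma0: float, G: float, tau_r: float,
                         t_grid: np.ndarray) -> np.ndarray:
    """Integrate simple-shear creep of one element under constant traction.

    Massless Kelvin--Voigt balance: eta_c dgamma/dt = sigma0 - sigma_el(gamma),
    where sigma_el comes from the assembled elastic nodal forces.  For the
    neo-Hookean element sigma_el = G gamma exactly, so the result must
    follow kv_step_response(sigma0, G, tau_r, t).
    """
    eta_c = tau_r * G
    mat = MaterialParams(G=G, eta_c=eta_c, tau_r=tau_r)
    t_grid = np.asarray(t_grid, dtype=float)
    dt = tau_r / 400.0
    out = np.empty_like(t_grid)
    gamma, t = 0.0, 0.0
    for k, tk in enumerate(t_grid):
        while t < tk - 1e-15:
            step = min(dt, tk - t)
            gamma += step * (sigma0 - element_shear_stress(gamma, mat)) / eta_c
            t += step
        out[k] = gamma
    return out


def spreading_conservation_error(seed: int = 0) -> float:
    """Max relative mismatch between total nodal and total spread force."""
    geom = ChannelGeometry(channel_length=60.0, reservoir_length=0.0,
                           reservoir_width=20.0)
    h = geom.width_m / 16
    grid = build_grid(geom, h)
    mesh = build_disk_mesh(10e-6, 1.2e-6,
                           center=(grid.Lx / 2, grid.Ly / 2))
    rng = np.random.default_rng(seed)
    forces = rng.normal(0.0, 1e-9, mesh.cur_nodes.shape)
    f_u, f_v = spread_forces(forces, mesh, grid)
    tot_u = f_u.sum() * h * h
    tot_v = f_v.sum() * h * h
    scale = np.abs(forces).sum()
    return float(max(abs(tot_u - forces[:, 0].sum()),
                     abs(tot_v - forces[:, 1].sum())) / scale)


def rigid_limit_di(G: float = 5e4) -> float:
    """Steady DI of a very stiff cell in a short channel (rigid proxy).

    The dashpot is held at the baseline cell's value (eta_c = 20 mPa.s)
    so only the elastic stiffness is taken to its limit.
    """
    cfg = SimConfig.from_dict({
        "geometry": {"channel_length": 60.0, "reservoir_length": 30.0,
                     "reservoir_width": 40.0},
        "fluid": {"flow_rate": 20.0, "viscosity": 1.0},
        "cell": {"young_modulus": 3.0 * G, "cell_viscosity": 20.0},
        "solver": {"grid_spacing": 1.25, "output_stride": 50},
    })
    return run_transit(cfg).steady_value("DI")


def run_verification(fast: bool = False) -> list[dict]:
    """Run the oracle suite; returns a list of {name, ok, detail} dicts."""
    results = []

    err = poiseuille_l2_error()
    results.append({
        "name": "poiseuille_profile",
        "ok": err <= 0.01,
        "detail": f"L2 error {err:.3%} (limit 1%)",
    })

    tau_r, G, sigma0 = 1e-4, 500.0, 10.0
    t = np.linspace(0.1 * tau_r, 5 * tau_r, 12)
    num = kv_creep_via_element(sigma0, G, tau_r, t)
    ref = kv_step_response(sigma0, G, tau_r, t)
    kv_err = float(np.abs(num - ref).max() / (sigma0 / G))
    results.append({
        "name": "kelvin_voigt_creep",
        "ok": kv_err <= 0.01,
        "detail": f"max deviation {kv_err:.3%} of plateau (limit 1%)",
    })

    cons = spreading_conservation_error()
    results.append({
        "name": "force_spreading_conservation",
        "ok": cons <= 1e-12,
        "detail": f"relative mismatch {cons:.2e} (limit 1e-12)",
    })

    if not fast:
        di = rigid_limit_di()
        results.append({
            "name": "rigid_limit",
            "ok": di - 1.0 <= 0.05,
            "detail": f"DI - 1 = {di - 1:.4f} at G = 5e4 Pa (limit 0.05)",
        })
    return results
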