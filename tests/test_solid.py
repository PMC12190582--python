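"""Disk meshing, hyperelastic/viscous force assembly, Kelvin--Voigt creep."""

import numpy as np
import pytest

from defcytosim.errors import ElementInversionError, ResolutionError
from defcytosim.solid import (
    CellMesh,
    MaterialParams,
    build_disk_mesh,
    cell_area,
    elastic_energy,
    elastic_forces,
    kv_step_response,
    viscous_forces,
)
from defcytosim.verify import element_shear_stress, kv_creep_via_element

MAT = MaterialParams(G=500.0, eta_c=0.02, tau_r=4e-5)


def rotate(nodes, angle, about):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return (nodes - about) @ R.T + about


class TestDiskMesh:
    def test_reference_area_matches_disk(self):
        mesh = build_disk_mesh(10e-6, 10e-6 / 16)
        assert cell_area(mesh) == pytest.approx(np.pi * (5e-6) ** 2, rel=5e-3)
        assert mesh.ref_areas.sum() == pytest.approx(cell_area(mesh), rel=1e-12)

    def test_deterministic(self):
        m1 = build_disk_mesh(12e-6, 1e-6)
        m2 = build_disk_mesh(12e-6, 1e-6)
        assert np.array_equal(m1.ref_nodes, m2.ref_nodes)
        assert np.array_equal(m1.triangles, m2.triangles)

    def test_boundary_node_count(self):
        mesh = build_disk_mesh(16e-6, 1e-6)
        assert len(mesh.boundary) >= 48
        # boundary loop is the outermost ring, at radius ~ diameter/2
        r = np.linalg.norm(mesh.contour, axis=1)
        assert np.allclose(r, 8e-6, rtol=1e-9)

    def test_too_coarse_edge_rejected(self):
        with pytest.raises(ResolutionError):
            build_disk_mesh(8e-6, 2e-6)

    def test_positively_oriented_conforming(self):
        mesh = build_disk_mesh(12e-6, 1.2e-6)
        assert (mesh.ref_areas > 0).all()
        # every boundary edge belongs to exactly one triangle
        from collections import Counter
        edges = Counter()
        for t in mesh.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                edges[frozenset((t[a], t[b]))] += 1
        n_boundary_edges = sum(1 for c in edges.values() if c == 1)
        assert n_boundary_edges == len(mesh.boundary)


class TestElasticForces:
    def test_zero_at_reference(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        f = elastic_forces(mesh, MAT)
        assert np.abs(f).max() < 1e-12 * MAT.G * 10e-6

    def test_zero_under_rigid_rotation(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        mesh.cur_nodes = rotate(mesh.ref_nodes, np.deg2rad(30), mesh.ref_nodes.mean(0))
        f = elastic_forces(mesh, MAT)
        assert np.abs(f).max() < 1e-12 * MAT.G * 10e-6

    def test_momentum_and_torque_conservation(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        rng = np.random.default_rng(11)
        mesh.cur_nodes = mesh.ref_nodes + 0.02 * 5e-6 * rng.standard_normal(
            mesh.ref_nodes.shape)
        f = elastic_forces(mesh, MAT)
        scale = np.abs(f).sum()
        assert np.abs(f.sum(axis=0)).max() < 1e-12 * scale
        r = mesh.cur_nodes - mesh.cur_nodes.mean(0)
        torque = (r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]).sum()
        assert abs(torque) < 1e-12 * scale * 5e-6

    def test_forces_are_energy_gradient(self):
        """-dW/dx via central differences on 20 seeded random configurations."""
        mesh = build_disk_mesh(10e-6, 1.2e-6)
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = mesh.copy()
            m.cur_nodes = mesh.ref_nodes + 0.03 * 5e-6 * rng.standard_normal(
                mesh.ref_nodes.shape)
            f = elastic_forces(m, MAT)
            i = int(rng.integers(m.n_nodes))
            d = int(rng.integers(2))
            eps = 1e-4 * 5e-6
            mp, mm = m.copy(), m.copy()
            mp.cur_nodes = m.cur_nodes.copy()
            mm.cur_nodes = m.cur_nodes.copy()
            mp.cur_nodes[i, d] += eps
            mm.cur_nodes[i, d] -= eps
            fd = -(elastic_energy(mp, MAT) - elastic_energy(mm, MAT)) / (2 * eps)
            assert fd == pytest.approx(f[i, d], rel=1e-6, abs=1e-18)

    def test_small_strain_stiffness_is_plane_strain_modulus(self):
        """Isochoric uniaxial stretch recovers the 4G plane-strain modulus."""
        mesh = build_disk_mesh(10e-6, 1e-6)
        eps = 1e-4
        m = mesh.copy()
        m.cur_nodes = mesh.ref_nodes * np.array([1 + eps, 1 / (1 + eps)])
        W = elastic_energy(m, MAT)
        area = mesh.ref_areas.sum()
        # W ~ (1/2) * (4G) * eps^2 * area for the incompressible mode
        modulus = 2 * W / (eps ** 2 * area)
        assert modulus == pytest.approx(4 * MAT.G, rel=0.02)

    def test_inverted_element_raises(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        mesh.cur_nodes = mesh.ref_nodes * np.array([-1.0, 1.0])
        with pytest.raises(ElementInversionError):
            elastic_forces(mesh, MAT)


class TestViscousForces:
    def test_zero_for_uniform_translation(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        mesh.node_velocities = np.tile([0.3, -0.1], (mesh.n_nodes, 1))
        assert np.abs(viscous_forces(mesh, MAT)).max() == 0.0

    def test_zero_for_rigid_rotation(self):
        mesh = build_disk_mesh(10e-6, 1e-6)
        r = mesh.cur_nodes - mesh.cur_nodes.mean(0)
        mesh.node_velocities = 100.0 * np.column_stack([-r[:, 1], r[:, 0]])
        f = viscous_forces(mesh, MAT)
        assert np.abs(f).max() < 1e-12 * MAT.eta_c * 100.0

    def test_single_triangle_shear_matches_hand_assembly(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        mesh = CellMesh(
            ref_nodes=nodes, cur_nodes=nodes.copy(),
            node_velocities=np.zeros_like(nodes),
            triangles=np.array([[0, 1, 2]]), ref_areas=np.array([0.5]),
            boundary=np.array([0, 1, 2]), diameter=1.0,
        )
        gdot = 3.0
        mesh.node_velocities = np.column_stack([gdot * nodes[:, 1],
                                                np.zeros(3)])
        f = viscous_forces(mesh, MAT)
        s = MAT.eta_c * gdot
        expected = 0.5 * np.array([[s, s], [0.0, -s], [-s, 0.0]])
        assert f == pytest.approx(expected, rel=1e-12)


class TestKelvinVoigt:
    def test_step_response_limits(self):
        assert kv_step_response(10.0, 500.0, 1e-4, 0.0) == 0.0
        assert kv_step_response(10.0, 500.0, 1e-4, 1.0) == pytest.approx(10 / 500)
        assert kv_step_response(10.0, 500.0, 1e-4, 1e-4) == pytest.approx(
            0.6321 * 10 / 500, rel=1e-4)

    def test_single_element_creep_follows_closed_form(self):
        """Assembled-force integration of one element under constant shear
        traction reproduces the Kelvin--Voigt creep curve within 1%."""
        tau_r, G, sigma0 = 1e-4, 500.0, 10.0
        t = np.linspace(0.25 * tau_r, 5 * tau_r, 10)
        num = kv_creep_via_element(sigma0, G, tau_r, t)
        ref = kv_step_response(sigma0, G, tau_r, t)
        assert np.abs(num - ref).max() <= 0.01 * sigma0 / G

    def test_element_shear_stress_is_g_gamma(self):
        # neo-Hookean simple shear: sigma_12 = G * gamma exactly
        for g in (0.01, 0.2, 0.8):
            assert element_shear_stress(g, MAT) == pytest.approx(MAT.G * g, rel=1e-12)


def test_material_params_penalty_floor():
    with pytest.raises(ValueError):
        MaterialParams(G=500.0, eta_c=0.0, tau_r=0.0, kappa=500.0)
    m = MaterialParams(G=500.0, eta_c=0.0, tau_r=0.0)
    assert m.kappa == pytest.approx(100 * 500.0)
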