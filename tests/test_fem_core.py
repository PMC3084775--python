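import numpy as np
import pytest

import jawfem as jf
from jawfem.errors import GeometryError, ParameterError, SolverError
from jawfem.fem_core import (ConstraintSet, LinkGroup, assemble,
                             build_constraints, element_energies,
                             element_stiffness, recover_stress, solve_static,
                             total_strain_energy, von_mises_strain,
                             von_mises_stress)
from jawfem.geometry import build_beam_fixture, build_patch_cube

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def quadrature_stiffness(coords, E_gpa, nu):
    """Independent stiffness route: shape-function coefficients from the
    4x4 interpolation system, B assembled per node, midpoint quadrature
    (exact for constant-strain elements)."""
    E = E_gpa * 1e3
    A = np.hstack([np.ones((4, 1)), coords])         # N_a = alpha + beta.x
    C = np.linalg.inv(A)                             # rows: alpha, bx, by, bz
    grads = C[1:, :].T                               # (4, 3)
    vol = abs(np.linalg.det(A)) / 6.0
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a] = gy
        B[3, 3 * a + 1] = gx
        B[4, 3 * a + 1] = gz
        B[4, 3 * a + 2] = gy
        B[5, 3 * a] = gz
        B[5, 3 * a + 2] = gx
    return vol * B.T @ D @ B


class TestElementStiffness:
    def test_symmetry(self):
        K = element_stiffness(UNIT_TET, 20.0, 0.3)
        assert np.linalg.norm(K - K.T) == 0.0

    def test_rigid_translations_in_nullspace(self):
        K = element_stiffness(UNIT_TET, 20.0, 0.3)
        for ax in range(3):
            t = np.zeros(12)
            t[ax::3] = 1.0
            assert np.abs(K @ t).max() < 1e-9 * np.abs(K).max()

    def test_exactly_six_zero_eigenvalues(self):
        K = element_stiffness(UNIT_TET, 1.0, 0.25)
        w = np.linalg.eigvalsh(K)
        scale = w.max()
        assert (w > -1e-10 * scale).all()
        assert (np.abs(w) < 1e-10 * scale).sum() == 6

    def test_matches_independent_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            coords = UNIT_TET + 0.2 * rng.standard_normal((4, 3))
            if np.linalg.det(coords[1:] - coords[0]) <= 0:
                continue
            K1 = element_stiffness(coords, 1.0, 0.0)
            K2 = quadrature_stiffness(coords, 1.0, 0.0)
            assert np.allclose(K1, K2, atol=1e-9 * np.abs(K2).max())

    def test_inverted_tet_rejected(self):
        with pytest.raises(GeometryError):
            element_stiffness(UNIT_TET[[1, 0, 2, 3]], 20.0, 0.3)


class TestAssembly:
    def test_assembly_equals_scattered_elements(self):
        mesh = build_beam_fixture(1, 1, 1, 1)
        mats = jf.homogeneous_table(mesh, 5.0, 0.2)
        K = assemble(mesh, mats).toarray()
        K2 = np.zeros_like(K)
        for tet in mesh.tets:
            Ke = element_stiffness(mesh.nodes[tet], 5.0, 0.2)
            dof = (3 * tet[:, None] + np.arange(3)).ravel()
            K2[np.ix_(dof, dof)] += Ke
        assert np.allclose(K, K2, atol=1e-9 * np.abs(K2).max())

    def test_linearity_in_modulus(self):
        mesh = build_patch_cube()
        K1 = assemble(mesh, jf.homogeneous_table(mesh, 10.0, 0.3))
        K2 = assemble(mesh, jf.homogeneous_table(mesh, 20.0, 0.3))
        assert np.allclose(K2.toarray(), 2 * K1.toarray())

    def test_six_rigid_body_modes_before_constraints(self):
        mesh = build_patch_cube()
        K = assemble(mesh, jf.homogeneous_table(mesh, 20.0, 0.3))
        x = mesh.nodes
        modes = []
        for ax in range(3):
            t = np.zeros((len(x), 3))
            t[:, ax] = 1.0
            modes.append(t.ravel())
        for ax in range(3):
            w = np.zeros(3)
            w[ax] = 1.0
            modes.append(np.cross(np.broadcast_to(w, x.shape), x).ravel())
        scale = np.abs(K.data).max()
        for m in modes:
            assert np.abs(K @ m).max() < 1e-9 * scale


class TestSolve:
    def test_zero_load_gives_zero_state(self, mandible_l1, runner):
        from jawfem.sensitivity import ModelConfig
        K = runner.stiffness(ModelConfig(refine_level=1))
        cs = build_constraints(mandible_l1, jf.select_bite_nodes(mandible_l1, 1))
        res = solve_static(K, np.zeros((mandible_l1.n_nodes, 3)), cs)
        assert np.abs(res.displacement).max() == 0.0
        assert res.total_strain_energy == 0.0

    def test_patch_test_reproduces_linear_field_exactly(self):
        mesh = build_patch_cube()
        mats = jf.homogeneous_table(mesh, 20.0, 0.3)
        K = assemble(mesh, mats)
        A = np.array([[2e-4, 3e-5, -1e-5],
                      [3e-5, -1e-4, 2e-5],
                      [-1e-5, 2e-5, 5e-5]])  # symmetric strain field
        cs = ConstraintSet()
        for n in mesh.node_sets["boundary"]:
            cs.fix_node(int(n), mesh.nodes[n] @ A)
        res = solve_static(K, np.zeros((mesh.n_nodes, 3)), cs)
        expect = mesh.nodes @ A
        assert np.allclose(res.displacement, expect, atol=1e-12)
        stress, strain = recover_stress(mesh, mats, res.displacement)
        assert np.allclose(strain, strain[0], atol=1e-14)
        assert np.allclose(stress, stress[0], atol=1e-9)

    def test_uniaxial_patch_stress_matches_hooke_closed_form(self):
        mesh = build_patch_cube()
        E, nu, eps = 20.0, 0.3, 1e-4
        mats = jf.homogeneous_table(mesh, E, nu)
        K = assemble(mesh, mats)
        cs = ConstraintSet()
        for n in mesh.node_sets["boundary"]:
            cs.fix_node(int(n), (mesh.nodes[n, 0] * eps, 0.0, 0.0))
        res = solve_static(K, np.zeros((mesh.n_nodes, 3)), cs)
        stress, _ = recover_stress(mesh, mats, res.displacement)
        sxx = E * 1e3 * (1 - nu) / ((1 + nu) * (1 - 2 * nu)) * eps
        assert np.allclose(stress[:, 0, 0], sxx, rtol=1e-9)

    def test_cantilever_converges_toward_beam_theory(self):
        errs = []
        for res in (2, 4, 6):
            mesh = build_beam_fixture(100.0, 10.0, 10.0, res)
            mats = jf.homogeneous_table(mesh, 20.0, 0.3)
            K = assemble(mesh, mats)
            cs = ConstraintSet()
            cs.fix_nodes(mesh.node_sets["fixed_end"])
            loads = np.zeros((mesh.n_nodes, 3))
            tip = mesh.node_sets["tip"]
            loads[tip, 2] = -10.0 / len(tip)
            r = solve_static(K, loads, cs)
            tipz = -r.displacement[tip, 2].mean()
            errs.append(abs(tipz - 0.2) / 0.2)
        assert errs[0] > errs[1] > errs[2]

    def test_load_scaling_is_linear(self, beam_solution):
        mesh, mats, K, loads, res = beam_solution
        cs = ConstraintSet()
        cs.fix_nodes(mesh.node_sets["fixed_end"])
        res2 = solve_static(K, 3.0 * loads, cs)
        assert np.allclose(res2.displacement, 3.0 * res.displacement,
                           rtol=1e-9)
        assert res2.total_strain_energy == pytest.approx(
            9.0 * res.total_strain_energy, rel=1e-9)

    def test_doubling_modulus_halves_energy(self, beam_solution):
        mesh, mats, K, loads, res = beam_solution
        mats2 = jf.homogeneous_table(mesh, 40.0, 0.3)
        K2 = assemble(mesh, mats2)
        cs = ConstraintSet()
        cs.fix_nodes(mesh.node_sets["fixed_end"])
        res2 = solve_static(K2, loads, cs)
        assert res2.total_strain_energy == pytest.approx(
            res.total_strain_energy / 2, rel=1e-9)

    def test_unconstrained_system_raises(self):
        mesh = build_patch_cube()
        K = assemble(mesh, jf.homogeneous_table(mesh, 20.0, 0.3))
        loads = np.zeros((mesh.n_nodes, 3))
        loads[0, 2] = 1.0
        with pytest.raises(SolverError):
            solve_static(K, loads, ConstraintSet())

    def test_iterative_solver_agrees_with_direct(self, beam_solution):
        mesh, mats, K, loads, res = beam_solution
        cs = ConstraintSet()
        cs.fix_nodes(mesh.node_sets["fixed_end"])
        res2 = solve_static(K, loads, cs, method="cg")
        assert np.allclose(res2.displacement, res.displacement,
                           atol=1e-6 * np.abs(res.displacement).max())


class TestLinks:
    def test_linked_nodes_move_on_circle_about_axis(self, runner):
        from jawfem.sensitivity import ModelConfig
        rec, res, mesh, ex = runner.solve(
            ModelConfig(refine_level=1, tmj_mode="row_links"))
        cs = build_constraints(mesh, ex["bite_nodes"], "row_links")
        for grp in cs.link_groups:
            theta = res.link_theta[grp.label]
            for node, arm in zip(grp.linked_nodes, grp.arms):
                u = res.displacement[int(node)]
                assert np.allclose(u, theta * arm, atol=1e-10)

    def test_link_group_requires_unit_axis(self):
        with pytest.raises(ParameterError):
            LinkGroup(axis_point=np.zeros(3),
                      axis_direction=np.array([0.0, 2.0, 0.0]),
                      linked_nodes=np.array([0]))

    def test_fixed_and_linked_dof_overlap_rejected(self):
        g = LinkGroup(axis_point=np.zeros(3),
                      axis_direction=np.array([0.0, 1.0, 0.0]),
                      linked_nodes=np.array([3]))
        g.arms = np.array([[1.0, 0.0, 0.0]])
        cs = ConstraintSet(link_groups=[g])
        cs.fix_node(3)
        with pytest.raises(ParameterError):
            cs.validate()


class TestRecovery:
    def test_rigid_motion_produces_zero_stress(self, mandible_l1):
        mats = jf.homogeneous_table(mandible_l1, 20.0, 0.3)
        u = np.tile([1.0, -2.0, 0.5], (mandible_l1.n_nodes, 1))
        stress, strain = recover_stress(mandible_l1, mats, u)
        assert np.abs(stress).max() < 1e-9

    def test_energy_consistency_two_routes(self, beam_solution):
        mesh, mats, K, loads, res = beam_solution
        stress, strain = recover_stress(mesh, mats, res.displacement)
        U_elem = element_energies(mesh, stress, strain).sum()
        U_work = total_strain_energy(res.displacement, loads)
        assert U_elem == pytest.approx(U_work, rel=1e-8)
        assert U_work == pytest.approx(res.total_strain_energy, rel=1e-8)

    def test_uniform_stress_block_energy_closed_form(self):
        # uniaxial stress sigma in a 1000 mm^3 block: U = sigma^2 V / 2E
        L, w, h = 10.0, 10.0, 10.0
        E, delta = 20.0, 5e-3  # eps = 5e-4 -> sigma = 10 MPa
        mesh = build_beam_fixture(L, w, h, 2)
        mats = jf.homogeneous_table(mesh, E, 0.0)
        K = assemble(mesh, mats)
        cs = ConstraintSet()
        for n in mesh.node_sets["fixed_end"]:
            cs.fix_node(int(n))
        for n in mesh.node_sets["tip"]:
            cs.fix_node(int(n), (delta, 0.0, 0.0))
        res = solve_static(K, np.zeros((mesh.n_nodes, 3)), cs)
        sigma = E * 1e3 * delta / L
        U = sigma ** 2 * (L * w * h) / (2 * E * 1e3) * 1e-3
        assert res.total_strain_energy == pytest.approx(U, rel=1e-9)
        assert U == pytest.approx(0.0025, rel=1e-12)


class TestVonMises:
    def test_uniaxial_stress(self):
        t = np.diag([10.0, 0.0, 0.0])
        assert von_mises_stress(t) == pytest.approx(10.0)

    def test_hydrostatic_is_zero(self):
        assert von_mises_stress(np.eye(3) * 7.5) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_strain_consistency(self):
        # uniaxial stress sigma=10 MPa, E=20 GPa, nu=0.3 -> eps_vm = sigma/E
        E, nu, sigma = 20.0e3, 0.3, 10.0
        eps = np.diag([sigma / E, -nu * sigma / E, -nu * sigma / E])
        assert von_mises_strain(eps, nu) == pytest.approx(sigma / E, rel=1e-12)

    def test_asymmetric_tensor_rejected(self):
        t = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ParameterError):
            von_mises_stress(t)
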