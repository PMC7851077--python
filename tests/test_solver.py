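"""FE solver: element integration, assembly, patch test, failure runs."""

import numpy as np
import pytest

import vertfe as vf
from vertfe.materials import MaterialTable, elasticity_tensor
from vertfe.solver import FEModel, _constraints, element_stiffness, solve_static

from conftest import cube_phantom


def quadrature_stiffness(verts, c, n_seed=0):
    """Independent oracle: K = sum_q w_q B(x_q)^T C B(x_q) with shape-function
    gradients obtained by central finite differences of the barycentric
    coordinates (no analytic inverse-Jacobian formula)."""
    verts = np.asarray(verts, dtype=np.float64)

    def bary(x):
        a = np.vstack([np.ones(4), verts.T])
        return np.linalg.solve(a, np.concatenate([[1.0], x]))

    vol = abs(np.linalg.det(verts[1:] - verts[0])) / 6.0
    # degree-2 Gauss points for a tetrahedron, weights V/4
    a, b = 0.5854101966249685, 0.1381966011250105
    qpts = []
    for i in range(4):
        lam = np.full(4, b)
        lam[i] = a
        qpts.append(lam @ verts)
    k = np.zeros((12, 12))
    h = 1e-5
    for x in qpts:
        grads = np.zeros((4, 3))
        for d in range(3):
            dx = np.zeros(3)
            dx[d] = h
            grads[:, d] = (bary(x + dx) - bary(x - dx)) / (2 * h)
        bmat = np.zeros((6, 12))
        for node in range(4):
            bx, by, bz = grads[node]
            col = 3 * node
            bmat[0, col] = bx
            bmat[1, col + 1] = by
            bmat[2, col + 2] = bz
            bmat[3, col + 1] = bz
            bmat[3, col + 2] = by
            bmat[4, col] = bz
            bmat[4, col + 2] = bx
            bmat[5, col] = by
            bmat[5, col + 1] = bx
        k += (vol / 4.0) * bmat.T @ c @ bmat
    return k


def constant_material(hu=200.0, n=1):
    return MaterialTable(np.full(n, hu))


class TestElementStiffness:
    def unit_tet(self):
        return np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )

    def test_symmetry(self):
        ke = element_stiffness(self.unit_tet(), constant_material()[0])
        assert np.allclose(ke, ke.T, atol=1e-12)

    def test_rigid_translations_in_null_space(self):
        ke = element_stiffness(self.unit_tet(), constant_material()[0])
        for d in range(3):
            u = np.zeros(12)
            u[d::3] = 1.0
            assert np.allclose(ke @ u, 0.0, atol=1e-10)

    def test_matches_quadrature_oracle(self):
        mat = constant_material(300.0)[0]
        verts = np.array(
            [[0.1, 0.0, 0.2], [1.3, 0.1, 0.0], [0.2, 1.1, 0.3], [0.4, 0.2, 1.4]]
        )
        ke = element_stiffness(verts, mat)
        c = elasticity_tensor(mat.Ez, mat.nu_xy, mat.nu_xz)
        oracle = quadrature_stiffness(verts, c)
        assert np.allclose(ke, oracle, rtol=1e-6, atol=1e-6 * np.abs(ke).max())

    def test_degenerate_element_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            element_stiffness(flat, constant_material()[0])


class TestAssembly:
    def test_single_element_equals_element_matrix(self):
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        mesh = vf.TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        mats = constant_material(n=1)
        k = vf.assemble(mesh, mats).toarray()
        ke = element_stiffness(nodes, mats[0])
        assert np.allclose(k, ke)

    def test_disconnected_elements_are_block_diagonal(self):
        nodes = np.array(
            [
                [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                [5, 5, 5], [6, 5, 5], [5, 6, 5], [5, 5, 6],
            ],
            dtype=float,
        )
        mesh = vf.TetMesh(
            nodes, np.array([[0, 1, 2, 3], [4, 5, 6, 7]]), np.array([1, 1])
        )
        k = vf.assemble(mesh, constant_material(n=2)).toarray()
        assert np.allclose(k[:12, 12:], 0.0)
        assert np.allclose(k[12:, :12], 0.0)

    def test_global_translation_in_null_space(self, tiny_phantom):
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        k = vf.assemble(mesh, vf.map_mesh(mesh, img, mask))
        u = np.zeros(k.shape[0])
        u[2::3] = 1.0
        assert np.abs(k @ u).max() < 1e-8 * np.abs(k.data).max()


class TestStaticSolve:
    def patch_model(self, eps=-1e-3, hu=200.0):
        img, mask = cube_phantom((3, 3, 3), hu=hu)
        mesh = vf.voxel_to_tet(mask, img, 1.0)
        mats = MaterialTable(np.full(mesh.n_elements, hu))
        model = FEModel(mesh, mats)
        k = model.stiffness()
        xyz = mesh.nodes
        on_bound = np.any((xyz == xyz.min(0)) | (xyz == xyz.max(0)), axis=1)
        bnodes = np.nonzero(on_bound)[0]
        dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
        vals = np.zeros(len(dofs))
        vals[2::3] = eps * xyz[bnodes, 2]
        return mesh, mats, model, k, dofs, vals

    def test_zero_dirichlet_gives_zero_solution(self):
        mesh, mats, model, k, dofs, vals = self.patch_model()
        u, r = solve_static(k, dofs, np.zeros(len(dofs)))
        assert np.allclose(u, 0.0)
        assert np.allclose(r, 0.0)

    def test_linearity_in_prescribed_displacement(self):
        mesh, mats, model, k, dofs, vals = self.patch_model()
        u1, _ = solve_static(k, dofs, vals)
        u2, _ = solve_static(k, dofs, 2 * vals)
        assert np.allclose(u2, 2 * u1, rtol=1e-12, atol=1e-15)

    def test_patch_uniform_strain_and_reaction(self):
        """Linear boundary displacements must reproduce the uniform stress
        state exactly and the platen reaction must match sigma_zz * A."""
        eps = -1e-3
        mesh, mats, model, k, dofs, vals = self.patch_model(eps)
        u, r = solve_static(k, dofs, vals)
        stress, _ = model.stresses(u)
        c = elasticity_tensor(mats.Ez[0])
        expected = c @ np.array([0, 0, eps, 0, 0, 0])
        assert np.allclose(stress, expected[None, :], rtol=1e-8, atol=1e-8)
        top = np.nonzero(mesh.nodes[:, 2] == mesh.nodes[:, 2].max())[0]
        reaction = r[3 * top + 2].sum()
        area = 9.0
        assert np.isclose(reaction, expected[2] * area, rtol=1e-8)

    def test_principal_stresses_on_patch_state(self):
        eps = -1e-3
        mesh, mats, model, k, dofs, vals = self.patch_model(eps)
        u, _ = solve_static(k, dofs, vals)
        s1, s3 = vf.element_principal_stresses(u, mesh, mats)
        c = elasticity_tensor(mats.Ez[0])
        szz = c[2, 2] * eps
        sxx = c[0, 2] * eps
        assert np.allclose(s3, szz, rtol=1e-8)
        assert np.allclose(s1, sxx, rtol=1e-8)

    def test_principal_stresses_invariant_under_z_rotation(self):
        """Transverse isotropy about z: rotating geometry and displacements
        about z leaves the principal stresses unchanged."""
        eps = -1e-3
        mesh, mats, model, k, dofs, vals = self.patch_model(eps)
        u, _ = solve_static(k, dofs, vals)
        s1_ref, s3_ref = vf.element_principal_stresses(u, mesh, mats)
        th = np.deg2rad(30)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        mesh_rot = vf.TetMesh(mesh.nodes @ rot.T, mesh.tets, mesh.element_label)
        u_rot = (u.reshape(-1, 3) @ rot.T).ravel()
        s1, s3 = vf.element_principal_stresses(u_rot, mesh_rot, mats)
        assert np.allclose(s1, s1_ref, rtol=1e-8, atol=1e-10)
        assert np.allclose(s3, s3_ref, rtol=1e-8, atol=1e-10)

    def test_singular_system_raises(self):
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        mesh = vf.TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
        k = vf.assemble(mesh, constant_material(n=1))
        with pytest.raises(RuntimeError):
            solve_static(k, np.array([0]), np.array([0.1]))

    def test_zero_prescribed_increment(self, tiny_phantom):
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        vf.extract_boundary_sets(mesh)
        mats = vf.map_mesh(mesh, img, mask)
        k = vf.assemble(mesh, mats)
        bc = vf.platen_conditions(mesh)
        u, f = vf.solve_increment(k, bc, 0.0)
        assert np.allclose(u, 0.0)
        assert f == 0.0


class TestRunCompression:
    def cuboid_model(self, nx=5, nz=20, hu=180.0, nu=None):
        img, mask = cube_phantom((nx, nx, nz))
        mesh = vf.voxel_to_tet(mask, img, 1.0)
        vf.extract_boundary_sets(mesh, 0.02)
        if nu is None:
            mats = MaterialTable(np.full(mesh.n_elements, hu))
        else:
            mats = MaterialTable(np.full(mesh.n_elements, hu), nu_xy=nu, nu_xz=nu)
        return mesh, mats

    def test_knockdown_one_disables_damage(self, tiny_phantom):
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        vf.extract_boundary_sets(mesh)
        mats = vf.map_mesh(mesh, img, mask)
        bc = vf.platen_conditions(mesh, 0.004, 8)
        res = vf.run_compression(
            mesh, mats, bc, vf.SolverOptions(knockdown_factor=1.0)
        )
        assert res.n_failed_total == 0
        f = res.reaction_forces
        assert np.allclose(np.diff(f), f[1] - f[0], rtol=1e-9)
        assert res.failure_load == f[-1]

    def test_curve_starts_at_origin_and_damage_is_monotone(self, tiny_phantom):
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        vf.extract_boundary_sets(mesh)
        mats = vf.map_mesh(mesh, img, mask)
        bc = vf.platen_conditions(mesh)
        res = vf.run_compression(mesh, mats, bc)
        assert res.displacements[0] == 0.0
        assert res.reaction_forces[0] == 0.0
        assert (res.failed_elements_per_increment >= 0).all()
        assert res.failed_elements_per_increment.sum() == res.n_failed_total
        assert res.failure_load == res.reaction_forces.max()

    def test_equilibrium_at_every_increment(self, tiny_phantom):
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        vf.extract_boundary_sets(mesh)
        mats = vf.map_mesh(mesh, img, mask)
        res = vf.run_compression(mesh, mats, vf.platen_conditions(mesh))
        assert res.equilibrium_residuals.max() < 1e-8

    def test_homogeneous_cuboid_fails_near_strength_times_area(self):
        """Long uniform specimen with nu = 0 (so the platen constraint is
        inert and the stress state exactly uniaxial): the peak force matches
        sigma_min * cross-section up to the increment resolution."""
        mesh, mats = self.cuboid_model(nx=5, nz=20, hu=180.0, nu=0.0)
        bc = vf.BoundaryConditions(
            fixed_nodes=mesh.node_sets["inferior_body"],
            driven_nodes=mesh.node_sets["superior_body"],
            total_displacement=-0.004 * 20.0,
            n_increments=40,
        )
        res = vf.run_compression(mesh, mats, bc)
        area = 25.0
        expected = mats.sigma_min[0] * area
        assert abs(res.failure_load - expected) / expected < 0.10

    def test_strength_and_displacement_scaling_is_exact(self, tiny_phantom):
        """Piecewise-linear load path: scaling all stress limits and the
        prescribed displacement by k=2 scales every reaction by exactly 2."""
        img, mask = tiny_phantom
        mesh = vf.voxel_to_tet(mask, img, 2.5)
        vf.extract_boundary_sets(mesh)
        mats = vf.map_mesh(mesh, img, mask)
        bc1 = vf.platen_conditions(mesh, 0.004, 10)
        res1 = vf.run_compression(mesh, mats, bc1)
        bc2 = vf.BoundaryConditions(
            bc1.fixed_nodes, bc1.driven_nodes, 2 * bc1.total_displacement, 10
        )
        res2 = vf.run_compression(mesh, mats.scaled_strength(2.0), bc2)
        assert res1.n_failed_total == res2.n_failed_total
        assert np.array_equal(2 * res1.reaction_forces, res2.reaction_forces)
        assert res2.failure_load == 2 * res1.failure_load
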