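"""Stiffness assembly, surface loads and the linear solve."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from ablaquant.elasticity import (MatchOptions, MaterialParams, SolverOptions,
                                  StiffnessSolver, assemble_stiffness,
                                  build_surface_load, element_stiffness,
                                  match_surfaces, outer_boundary_nodes)
from ablaquant.errors import ConstraintError, CorrespondenceError
from ablaquant.hexmesh import build_mesh, shape_function_gradients
from ablaquant.imaging_io import LabelMap


@pytest.fixture(scope="module")
def bar_mesh():
    """10 x 1 x 1 mm bar of unit cross-section, 1 mm elements."""
    lab = np.zeros((12, 3, 3), dtype=np.int32)
    lab[1:11, 1, 1] = 1
    return build_mesh(LabelMap(lab), 1.0, 1.0, margin=0.0)


class TestElementStiffness:
    def test_symmetric_and_annihilates_rigid_translation(self, soft_tissue):
        ke = element_stiffness((1.0, 1.0, 1.0), soft_tissue)
        assert ke.shape == (24, 24)
        assert np.abs(ke - ke.T).max() < 1e-10
        for t in np.eye(3):
            assert np.abs(ke @ np.tile(t, 8)).max() < 1e-10

    def test_linear_in_youngs_modulus(self):
        k1 = element_stiffness((1.0, 1.0, 1.0), MaterialParams(30.0, 0.45))
        k2 = element_stiffness((1.0, 1.0, 1.0), MaterialParams(60.0, 0.45))
        assert np.allclose(k2, 2.0 * k1)

    def test_matches_high_order_quadrature_oracle(self, soft_tissue):
        # brute-force integration of the B^T C B integrand at 10x order
        size = (1.3, 0.8, 2.1)
        ke = element_stiffness(size, soft_tissue)
        oracle = _brute_force_stiffness(size, soft_tissue, n=10)
        assert np.abs(ke - oracle).max() / np.abs(oracle).max() < 1e-6

    def test_material_invariants(self):
        with pytest.raises(ValueError):
            MaterialParams(-1.0, 0.45)
        with pytest.raises(ValueError):
            MaterialParams(30.0, 0.5)


def _brute_force_stiffness(size, material, n=10):
    """Independent oracle: direct Gauss-Legendre integration at order n."""
    half = np.asarray(size) / 2.0
    pts, wts = np.polynomial.legendre.leggauss(n)
    c = material.elastic_matrix()
    ke = np.zeros((24, 24))
    for i, wi in zip(pts, wts):
        for j, wj in zip(pts, wts):
            for k, wk in zip(pts, wts):
                g = shape_function_gradients(np.array([i, j, k])) / half
                b = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = g[a]
                    b[0, 3 * a], b[1, 3 * a + 1], b[2, 3 * a + 2] = bx, by, bz
                    b[3, 3 * a], b[3, 3 * a + 1] = by, bx
                    b[4, 3 * a + 1], b[4, 3 * a + 2] = bz, by
                    b[5, 3 * a], b[5, 3 * a + 2] = bz, bx
                ke += wi * wj * wk * np.prod(half) * (b.T @ c @ b)
    return ke


class TestAssemblyAndSolve:
    def test_global_matrix_symmetric(self, bar_mesh, soft_tissue):
        k = assemble_stiffness(bar_mesh, soft_tissue)
        assert abs(k - k.T).max() < 1e-8 * abs(k).max()

    def test_no_constraints_raises(self, bar_mesh, soft_tissue):
        k = assemble_stiffness(bar_mesh, soft_tissue)
        with pytest.raises(ConstraintError):
            StiffnessSolver(k, {})

    def test_zero_force_zero_solution(self, bar_mesh, soft_tissue):
        k = assemble_stiffness(bar_mesh, soft_tissue)
        fixed = {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0,
                 30: 0.0, 31: 0.0, 32: 0.0}
        solver = StiffnessSolver(k, fixed)
        u, _ = solver.solve(np.zeros(k.shape[0]))
        assert np.abs(u).max() == 0.0

    def test_uniaxial_bar_matches_hookes_law(self, bar_mesh):
        # nu ~ 0: tip displacement F L / (E A) within 1%
        mat = MaterialParams(30.0, 1e-4)
        k = assemble_stiffness(bar_mesh, mat)
        lo, hi = bar_mesh.bounds()
        left = np.nonzero(np.isclose(bar_mesh.node_coords[:, 0], lo[0]))[0]
        right = np.nonzero(np.isclose(bar_mesh.node_coords[:, 0], hi[0]))[0]
        fixed = {3 * n + d: 0.0 for n in left for d in range(3)}
        f_ax = 0.6  # mN over the 1 mm^2 tip face
        forces = np.zeros(k.shape[0])
        forces[3 * right] = f_ax / len(right)
        solver = StiffnessSolver(k, fixed, SolverOptions(tol=1e-10))
        u, tele = solver.solve(forces)
        tip = u.reshape(-1, 3)[right, 0].mean()
        expected = f_ax * 10.0 / (30.0 * 1.0)
        assert tip == pytest.approx(expected, rel=0.01)
        assert tele["relative_residual"] < 1e-8

    def test_solution_linear_in_forces(self, bar_mesh, soft_tissue, rng):
        k = assemble_stiffness(bar_mesh, soft_tissue)
        boundary = outer_boundary_nodes(bar_mesh)
        fixed = {3 * n + d: 0.0
                 for n in boundary[bar_mesh.node_coords[boundary, 0] < 1]
                 for d in range(3)}
        solver = StiffnessSolver(k, fixed, SolverOptions(tol=1e-10))
        f = rng.normal(size=k.shape[0]) * 0.01
        u1, _ = solver.solve(f)
        u3, _ = solver.solve(3.0 * f)
        assert np.allclose(u3, 3.0 * u1, atol=1e-8 * np.abs(u1).max() + 1e-12)

    def test_bicgstab_matches_dense_direct_solve(self, soft_tissue, rng):
        # <= 5^3-element mesh: iterative and direct solutions agree
        lab = np.zeros((7, 7, 7), dtype=np.int32)
        lab[1:6, 1:6, 1:6] = 1
        mesh = build_mesh(LabelMap(lab), 1.0, 1.0, margin=0.0)
        k = assemble_stiffness(mesh, soft_tissue)
        boundary = outer_boundary_nodes(mesh)
        fixed = {3 * n + d: 0.0 for n in boundary for d in range(3)}
        f = rng.normal(size=k.shape[0]) * 0.01
        u_it, _ = StiffnessSolver(k, fixed, SolverOptions(tol=1e-10)).solve(f)
        u_dir, _ = StiffnessSolver(k, fixed,
                                   SolverOptions(method="direct")).solve(f)
        denom = max(np.linalg.norm(u_dir), 1e-300)
        assert np.linalg.norm(u_it - u_dir) / denom < 1e-6

    def test_patch_test_uniform_boundary_displacement(self, soft_tissue):
        # uniform Dirichlet displacement on the whole boundary reproduces a
        # uniform interior field to 1e-8 mm
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[1:7, 1:7, 1:7] = 1
        mesh = build_mesh(LabelMap(lab), 1.0, 1.0, margin=0.0)
        k = assemble_stiffness(mesh, soft_tissue)
        boundary = outer_boundary_nodes(mesh)
        shift = np.array([0.7, -0.3, 0.2])
        fixed = {3 * n + d: shift[d] for n in boundary for d in range(3)}
        u, _ = StiffnessSolver(k, fixed,
                               SolverOptions(method="direct")).solve(
            np.zeros(k.shape[0]))
        assert np.abs(u.reshape(-1, 3) - shift).max() < 1e-8

    def test_mirror_symmetry(self, soft_tissue):
        # mirror-symmetric mesh + mirror-symmetric load -> mirrored solution
        lab = np.zeros((8, 6, 6), dtype=np.int32)
        lab[1:7, 1:5, 1:5] = 1
        mesh = build_mesh(LabelMap(lab), 1.0, 1.0, margin=0.0)
        k = assemble_stiffness(mesh, soft_tissue)
        lo, hi = mesh.bounds()
        mid_x = (lo[0] + hi[0]) / 2
        boundary = outer_boundary_nodes(mesh)
        ends = boundary[np.isclose(mesh.node_coords[boundary, 0], lo[0])
                        | np.isclose(mesh.node_coords[boundary, 0], hi[0])]
        fixed = {3 * n + d: 0.0 for n in ends for d in range(3)}
        # load: +x force left of centre, -x force mirrored right of centre
        forces = np.zeros(k.shape[0])
        for n in range(mesh.n_nodes):
            x = mesh.node_coords[n, 0]
            if not np.isclose(x, mid_x):
                forces[3 * n] = 0.01 * np.sign(mid_x - x)
        u = StiffnessSolver(k, fixed,
                            SolverOptions(tol=1e-10)).solve(forces)[0]
        u = u.reshape(-1, 3)
        # pair nodes with their mirrors
        mirrored = mesh.node_coords.copy()
        mirrored[:, 0] = 2 * mid_x - mirrored[:, 0]
        from scipy.spatial import cKDTree
        _, pair = cKDTree(mesh.node_coords).query(mirrored)
        assert np.allclose(u[:, 0], -u[pair, 0], atol=1e-6)
        assert np.allclose(u[:, 1:], u[pair, 1:], atol=1e-6)

    def test_modulus_invariance_in_prescribed_mode(self, tiny_phantom):
        # with pure Dirichlet driving and homogeneous material, scaling E
        # leaves the solution unchanged
        _, labels = tiny_phantom
        mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
        from ablaquant.hexmesh import label_surface_points
        targets = {1: label_surface_points(labels, 1) + np.array([1.5, 0, 0])}
        sols = []
        for e_kpa in (30.0, 300.0):
            u, _ = match_surfaces(
                mesh, MaterialParams(e_kpa, 0.45), targets,
                MatchOptions(mode="prescribed",
                             solver=SolverOptions(tol=1e-10)))
            sols.append(u)
        assert np.allclose(sols[0], sols[1], atol=1e-6)


class TestSurfaceLoads:
    def test_identical_surfaces_zero_displacement(self, tiny_phantom):
        _, labels = tiny_phantom
        from ablaquant.hexmesh import label_surface_points
        mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
        load = build_surface_load(mesh, 2, label_surface_points(labels, 2))
        # voxelized cloud vs mesh nodes: sub-voxel mismatch only
        assert np.median(np.linalg.norm(load.displacements, axis=1)) < 1.0

    def test_translated_convex_target_recovers_shift(self, tiny_phantom):
        _, labels = tiny_phantom
        from ablaquant.hexmesh import label_surface_points
        mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
        shift = np.array([3.0, 0.0, 0.0])
        load = build_surface_load(mesh, 2,
                                  label_surface_points(labels, 2) + shift)
        med = np.median(load.displacements, axis=0)
        assert np.abs(med - shift).max() < 0.5

    def test_empty_target_raises(self, tiny_phantom):
        _, labels = tiny_phantom
        mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
        with pytest.raises(CorrespondenceError):
            build_surface_load(mesh, 2, np.empty((0, 3)))

    def test_gating_excludes_far_outliers(self, tiny_phantom, caplog):
        _, labels = tiny_phantom
        from ablaquant.hexmesh import label_surface_points
        mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
        pts = label_surface_points(labels, 2)
        load = build_surface_load(mesh, 2, pts, gating_mm=1.5)
        loose = build_surface_load(mesh, 2, pts, gating_mm=50.0)
        assert len(load.nodes) <= len(loose.nodes)


def test_elastic_system_solve_surface(bar_mesh, soft_tissue):
    """The ElasticSystem container round-trips through solve_displacements."""
    from ablaquant.elasticity import ElasticSystem, solve_displacements
    k = assemble_stiffness(bar_mesh, soft_tissue)
    lo, _ = bar_mesh.bounds()
    left = np.nonzero(np.isclose(bar_mesh.node_coords[:, 0], lo[0]))[0]
    forces = np.zeros(k.shape[0])
    forces[3 * (bar_mesh.n_nodes - 1)] = 0.1
    system = ElasticSystem(
        mesh=bar_mesh, material=soft_tissue, stiffness=k, forces=forces,
        fixed_dofs={3 * n + d: 0.0 for n in left for d in range(3)})
    u = solve_displacements(system, tol=1e-8)
    assert system.solution is u
    assert system.telemetry["relative_residual"] < 1e-6
    assert np.abs(u).max() > 0
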