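"""Solver verification: element math, assembly, loads, solutions, invariance."""
import numpy as np
import pytest
import scipy.sparse as sp

from conchmech import regions as R
from conchmech.fea_solver import (LoadCase, SolverError, StaticSolver, assemble,
                                  elasticity_matrix, element_stiffness,
                                  pressure_nodal_forces, solve)
from conchmech.geometry import SurfaceMesh, generate_sphere_midsurface
from conchmech.meshing import Material, TetModel, extract_boundary_faces, extrude_to_tets

from conftest import cube_patch_constraints

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
REGULAR_TET = np.array([[1, 1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, 1]], float) / np.sqrt(2)


def _rigid_modes(coords):
    """Six rigid-body mode vectors for a 4-node element."""
    modes = []
    for k in range(3):
        m = np.zeros((4, 3))
        m[:, k] = 1.0
        modes.append(m.ravel())
    for axis in np.eye(3):
        m = np.cross(np.broadcast_to(axis, (4, 3)), coords)
        modes.append(m.ravel())
    return modes


class TestElementStiffness:
    def test_symmetry(self):
        K = element_stiffness(UNIT_TET, Material())
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()

    def test_rigid_modes_in_null_space(self):
        K = element_stiffness(UNIT_TET, Material())
        for m in _rigid_modes(UNIT_TET):
            assert np.linalg.norm(K @ m) < 1e-8 * np.linalg.norm(K)

    def test_exactly_six_zero_eigenvalues(self):
        K = element_stiffness(REGULAR_TET, Material())
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w[:6]) < 1e-9 * w[-1]).all()
        assert w[6] > 1e-6 * w[-1]

    def test_quadrature_oracle(self):
        """K equals a midpoint-quadrature integral of B^T D B with B derived
        independently by finite differences of the linear shape functions."""
        mat = Material(young_modulus=1.0, poisson_ratio=0.0)
        coords = REGULAR_TET

        def shape_values(x):
            M = np.ones((4, 4))
            M[:, 1:] = coords
            rhs = np.concatenate([[1.0], x])
            return np.linalg.solve(M.T, rhs)

        h = 1e-6
        centroid = coords.mean(axis=0)
        grads = np.zeros((4, 3))
        for k in range(3):
            dx = np.zeros(3)
            dx[k] = h
            grads[:, k] = (shape_values(centroid + dx) - shape_values(centroid - dx)) / (2 * h)
        B = np.zeros((6, 12))
        for i in range(4):
            bx, by, bz = grads[i]
            c = 3 * i
            B[0, c], B[1, c + 1], B[2, c + 2] = bx, by, bz
            B[3, c], B[3, c + 1] = by, bx
            B[4, c + 1], B[4, c + 2] = bz, by
            B[5, c], B[5, c + 2] = bz, bx
        M4 = np.ones((4, 4))
        M4[:, 1:] = coords
        vol = abs(np.linalg.det(M4)) / 6.0
        K_oracle = vol * B.T @ elasticity_matrix(mat) @ B
        K = element_stiffness(coords, mat)
        assert np.abs(K - K_oracle).max() < 1e-8

    def test_degenerate_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(SolverError):
            element_stiffness(flat, Material())


def _two_tet_bar():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
    elements = np.array([[0, 1, 2, 3], [1, 4, 2, 3]])
    model = TetModel(nodes, elements, extract_boundary_faces(elements),
                     np.array(["validation"] * 8))
    vols = model.element_volumes()
    for i, v in enumerate(vols):
        if v < 0:
            model.elements[i] = model.elements[i][[0, 2, 1, 3]]
    model.boundary_faces = extract_boundary_faces(model.elements)
    model.boundary_labels = np.array(["validation"] * len(model.boundary_faces))
    return model


class TestAssembly:
    def test_dense_scatter_oracle(self):
        model = _two_tet_bar()
        K = assemble(model).toarray()
        n = 3 * len(model.nodes)
        K_oracle = np.zeros((n, n))
        for el in model.elements:
            Ke = element_stiffness(model.nodes[el], model.material)
            dofs = (3 * el[:, None] + np.arange(3)[None, :]).ravel()
            K_oracle[np.ix_(dofs, dofs)] += Ke
        assert np.abs(K - K_oracle).max() < 1e-9 * np.abs(K_oracle).max()

    def test_symmetry(self, small_shell_model):
        K = assemble(small_shell_model)
        d = abs(K - K.T)
        assert d.max() < 1e-8 * abs(K).max()

    def test_null_space_dimension_six(self):
        surf = generate_sphere_midsurface(5.0, 1)
        model = extrude_to_tets(surf, 0.5)
        K = assemble(model).toarray()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w[:6]) < 1e-8 * w[-1]).all()
        assert w[6] > 1e-8 * w[-1]


class TestPressureForces:
    def test_single_triangle_pa(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [1. / 3, 2. / 3, -1]], float)
        elements = np.array([[0, 1, 2, 3]])
        model = TetModel(nodes, elements, extract_boundary_faces(elements),
                         None)
        if model.element_volumes()[0] < 0:
            model.elements = elements[:, [0, 2, 1, 3]]
            model.boundary_faces = extract_boundary_faces(model.elements)
        # label the top face (area 1, normal +z)
        labels = []
        for f in model.boundary_faces:
            labels.append("top" if set(f) == {0, 1, 2} else "side")
        model.boundary_labels = np.array(labels)
        f = pressure_nodal_forces(model, {"top": 8.0})
        total = f.sum(axis=0)
        # area = 1 mm^2, p = 8 MPa -> resultant 8 N opposite the outward normal
        assert np.allclose(total, [0, 0, -8.0], atol=1e-12)

    def test_closed_sphere_equilibrium(self, sphere_model):
        f = pressure_nodal_forces(sphere_model, {R.EXTERNAL_WALL: 8.0})
        gross = np.linalg.norm(f, axis=1).sum()
        assert np.linalg.norm(f.sum(axis=0)) < 1e-8 * gross

    def test_flat_square_tributary_area(self, unit_square_surface):
        model = extrude_to_tets(unit_square_surface, 0.2)
        top = np.array([np.allclose(model.nodes[f][:, 2], 0.1)
                        for f in model.boundary_faces])
        labels = model.boundary_labels.astype(object)
        labels[top] = "top"
        model.boundary_labels = labels.astype(str)
        f = pressure_nodal_forces(model, {"top": 8.0})
        assert abs(np.linalg.norm(f.sum(axis=0)) - 8.0) < 1e-12
        # tributary oracle: each top face (area 1/2) sends p*A/3 to its 3 nodes
        top_faces = model.boundary_faces[top]
        oracle = np.zeros(len(model.nodes))
        for face in top_faces:
            for nidx in face:
                oracle[nidx] += 8.0 * 0.5 / 3.0
        assert np.allclose(np.abs(f[:, 2]), oracle, atol=1e-12)

    def test_missing_region_rejected(self, sphere_model):
        with pytest.raises(SolverError):
            pressure_nodal_forces(sphere_model, {"no_such_region": 1.0})


class TestSolve:
    def test_zero_load_zero_stress(self, sphere_model):
        fld = solve(sphere_model, LoadCase(), "minimal_321")
        assert np.abs(fld.displacement).max() < 1e-12
        assert np.abs(fld.element_stress).max() < 1e-12

    def test_uniaxial_patch_test(self, unit_cube_model):
        p = 8.0
        fixed = cube_patch_constraints(unit_cube_model)
        fld = solve(unit_cube_model,
                    LoadCase(pressure_by_region={"top": p}, fixed_nodes=fixed),
                    "fixed")
        szz = fld.element_stress[:, 2]
        assert np.abs(szz + p).max() < 1e-8
        others = np.delete(fld.element_stress, 2, axis=1)
        assert np.abs(others).max() < 1e-8

    def test_lame_hollow_sphere(self, sphere_model):
        from conchmech.fea_solver import nodal_average

        fld = solve(sphere_model, LoadCase(pressure_by_region={R.EXTERNAL_WALL: 8.0}),
                    "minimal_321")
        rr = np.linalg.norm(sphere_model.nodes, axis=1)
        inner = np.isclose(rr, 9.0, atol=1e-6)
        s3 = nodal_average(sphere_model, fld.principal[:, 2])
        exact = -3 * 8.0 * 10.0**3 / (2 * (10.0**3 - 9.0**3))
        assert abs(s3[inner].mean() / exact - 1) < 0.05

    def test_global_equilibrium(self, small_shell_hydro):
        fld = small_shell_hydro
        resid = fld.applied_force + fld.reaction_resultant()
        assert np.linalg.norm(resid) < 1e-6 * max(fld.gross_force, 1.0)

    def test_linearity(self, small_shell_model, small_shell_solver):
        from conchmech.load_cases import hydrostatic_case

        f1 = small_shell_solver.solve(hydrostatic_case(small_shell_model, 2.0))
        f2 = small_shell_solver.solve(hydrostatic_case(small_shell_model, 4.0))
        denom = np.abs(f2.nodal_max_principal).max()
        assert np.abs(f2.nodal_max_principal - 2 * f1.nodal_max_principal).max() \
            < 1e-6 * denom

    def test_frame_invariance(self):
        model = _two_tet_bar()
        case = LoadCase(point_loads={4: np.array([0.0, 0.0, -1.0])},
                        fixed_nodes={0: "xyz", 1: "yz", 2: "z"})
        fld = solve(model, case, "fixed")

        # rotate mesh, loads and constraint frame by a rigid rotation about z
        ang = 0.7
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        model2 = TetModel((Rz @ model.nodes.T).T, model.elements.copy(),
                          model.boundary_faces.copy(), model.boundary_labels.copy())
        # constraints must rotate too: use full clamps to stay frame-consistent
        case_a = LoadCase(point_loads={4: np.array([0.0, 0.0, -1.0])},
                          fixed_nodes={0: "xyz", 1: "xyz", 2: "xyz"})
        case_b = LoadCase(point_loads={4: Rz @ np.array([0.0, 0.0, -1.0])},
                          fixed_nodes={0: "xyz", 1: "xyz", 2: "xyz"})
        fa = solve(model, case_a, "fixed")
        fb = solve(model2, case_b, "fixed")
        assert np.abs(fa.principal - fb.principal).max() \
            < 1e-6 * np.abs(fa.principal).max()

    def test_dense_sparse_equivalence(self):
        model = _two_tet_bar()
        case = LoadCase(point_loads={4: np.array([1.0, 2.0, -3.0])},
                        fixed_nodes={0: "xyz", 1: "xyz", 2: "xyz"})
        fld = solve(model, case, "fixed")
        K = assemble(model).toarray()
        f = np.zeros(3 * len(model.nodes))
        f[12:15] = [1.0, 2.0, -3.0]
        fixed = np.arange(9)
        free = np.setdiff1d(np.arange(len(f)), fixed)
        u = np.zeros_like(f)
        u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
        assert np.abs(fld.displacement.ravel() - u).max() \
            < 1e-8 * np.abs(u).max()

    def test_principal_ordering(self, small_shell_hydro):
        p = small_shell_hydro.principal
        assert (p[:, 0] >= p[:, 1] - 1e-9).all()
        assert (p[:, 1] >= p[:, 2] - 1e-9).all()

    def test_inertia_relief_matches_321_on_balanced_load(self, sphere_model):
        case = LoadCase(pressure_by_region={R.EXTERNAL_WALL: 4.0})
        fa = solve(sphere_model, case, "minimal_321")
        fb = solve(sphere_model, case, "inertia_relief")
        denom = np.abs(fa.nodal_max_principal).max()
        assert np.abs(fa.nodal_max_principal - fb.nodal_max_principal).max() \
            < 1e-4 * denom

    def test_singular_without_constraints(self):
        model = _two_tet_bar()
        case = LoadCase(point_loads={4: np.array([0.0, 0.0, -1.0])})
        with pytest.raises(SolverError):
            StaticSolver(model, "fixed", fixed_nodes=None)
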