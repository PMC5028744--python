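"""Shared fixtures: small shells and solved fields reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

import conchmech as cm
from conchmech import regions as R
from conchmech.fea_solver import LoadCase, StaticSolver
from conchmech.geometry import ShellParams, SurfaceMesh, generate_planispiral_shell
from conchmech.load_cases import hydrostatic_case
from conchmech.meshing import Material, extrude_to_tets


def small_shell_params(**overrides) -> ShellParams:
    """A cheap synclastic shell used for unit tests."""
    kw = dict(
        initial_radius=8.0, whorl_expansion_rate=0.18, whorl_count=1.1,
        cross_section_aspect=1.2, wall_thickness=0.18, septum_thickness=0.12,
        septum_count=4, septum_type="synclastic", foramen_radius=0.4,
        body_chamber_fraction=0.35, rings_per_whorl=40, ring_segments=16,
        septum_rings=5,
    )
    kw.update(overrides)
    return ShellParams(**kw)


@pytest.fixture(scope="session")
def small_shell_surface() -> SurfaceMesh:
    return generate_planispiral_shell(small_shell_params())


@pytest.fixture(scope="session")
def small_shell_model(small_shell_surface):
    from conchmech.pipeline import region_thickness

    return extrude_to_tets(small_shell_surface,
                           region_thickness(small_shell_params()))


@pytest.fixture(scope="session")
def small_shell_solver(small_shell_model) -> StaticSolver:
    return StaticSolver(small_shell_model, "minimal_321")


@pytest.fixture(scope="session")
def small_shell_hydro(small_shell_model, small_shell_solver):
    """Hydrostatic 8 MPa solution on the small shell."""
    return small_shell_solver.solve(hydrostatic_case(small_shell_model, 8.0))


@pytest.fixture(scope="session")
def sphere_model():
    """Hollow sphere a=9, b=10 mm via mid-surface extrusion (coarse)."""
    surf = cm.generate_sphere_midsurface(9.5, 3)
    return extrude_to_tets(surf, 1.0, n_layers=2, material=Material())


@pytest.fixture(scope="session")
def unit_square_surface() -> SurfaceMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(verts, tris, np.array([R.VALIDATION] * 2))


@pytest.fixture(scope="session")
def unit_cube_model(unit_square_surface):
    """Unit cube of tets with the top face relabelled for traction loading."""
    model = extrude_to_tets(unit_square_surface, 1.0)
    top = np.array([np.allclose(model.nodes[f][:, 2], 0.5)
                    for f in model.boundary_faces])
    labels = model.boundary_labels.astype(object)
    labels[top] = "top"
    model.boundary_labels = labels.astype(str)
    model.node_sets["top"] = np.unique(model.boundary_faces[top])
    return model


def cube_patch_constraints(model) -> dict:
    """Bottom face fixed in z plus minimal in-plane restraints (free Poisson
    contraction)."""
    fixed = {i: "z" for i, n in enumerate(model.nodes) if np.isclose(n[2], -0.5)}

    def nid(pt):
        return int(np.argmin(np.linalg.norm(model.nodes - np.asarray(pt), axis=1)))

    a, b = nid((0, 0, -0.5)), nid((1, 0, -0.5))
    fixed[a] = "".join(sorted(set(fixed.get(a, "") + "xy")))
    fixed[b] = "".join(sorted(set(fixed.get(b, "") + "y")))
    return {k: "".join(sorted(set(v + "z"))) for k, v in fixed.items()}
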