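"""Static linear-elastic finite-element solver for TET4 meshes.

Constant-strain tetrahedra, isotropic material, mm-N-MPa unit system
(1 N/mm^2 = 1 MPa, so pressures in MPa on areas in mm^2 give forces in N).
Voigt order is [xx, yy, zz, xy, yz, zx] with engineering shear strains.
Tension is positive; the maximum principal stress sigma_1 is the largest
eigenvalue of the per-element stress tensor.

Pressure load cases on closed shells are (nearly) self-equilibrated; rather
than running an unconstrained singular system, the solver applies a minimal
3-2-1 constraint set at three deterministically chosen, mutually distant
nodes and verifies that the reactions are negligible, so the stress field is
unaffected.  An inertia-relief strategy is available for loads with a
residual resultant: the net force and moment are balanced by a rigid-body
inertial body force distributed over the lumped nodal masses before the
3-2-1 solve.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Material, TetModel

__all__ = [
    "LoadCase",
    "StressField",
    "element_stiffness",
    "elasticity_matrix",
    "assemble",
    "pressure_nodal_forces",
    "solve",
    "StaticSolver",
]


class SolverError(RuntimeError):
    pass


@dataclass
class LoadCase:
    """Pressure loads per boundary region, point loads per node, constraints.

    ``pressure_by_region``: region label -> pressure in MPa, positive pushing
    against the face (along the inward normal).  ``point_loads``: node index
    -> force vector in N.  ``fixed_nodes``: node index -> subset of "xyz".
    """

    pressure_by_region: Dict[str, float] = field(default_factory=dict)
    point_loads: Dict[int, np.ndarray] = field(default_factory=dict)
    fixed_nodes: Dict[int, str] = field(default_factory=dict)
    name: str = ""

    def validate(self) -> None:
        for n, comps in self.fixed_nodes.items():
            if not set(comps) <= set("xyz"):
                raise ValueError(f"invalid constraint components {comps!r} at node {n}")


@dataclass
class StressField:
    """Solution container: element stresses, principal stresses, nodal field."""

    element_stress: np.ndarray  # (ne, 6) Voigt, MPa
    principal: np.ndarray  # (ne, 3) sigma1 >= sigma2 >= sigma3, MPa
    nodal_max_principal: np.ndarray  # (nn,), MPa
    displacement: np.ndarray  # (nn, 3), mm
    reactions: Dict[int, np.ndarray] = field(default_factory=dict)
    applied_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gross_force: float = 0.0  # sum of |nodal force| magnitudes, N
    case_name: str = ""

    @property
    def sigma1(self) -> np.ndarray:
        return self.principal[:, 0]

    def reaction_resultant(self) -> np.ndarray:
        if not self.reactions:
            return np.zeros(3)
        return np.sum(list(self.reactions.values()), axis=0)


# ---------------------------------------------------------------------------
# element formulation
# ---------------------------------------------------------------------------

def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic elasticity matrix D (Voigt, engineering shear)."""
    material.validate()
    E, nu = material.young_modulus, material.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(coords: np.ndarray) -> Tuple[float, np.ndarray]:
    """Volume and (4, 3) shape-function gradients of one TET4."""
    M = np.ones((4, 4))
    M[:, 1:] = coords
    det = np.linalg.det(M)
    vol = det / 6.0
    if vol <= 0:
        raise SolverError(f"non-positive element volume {vol:.3e}")
    grads = np.linalg.inv(M)[1:, :].T  # row i: grad N_i
    return vol, grads


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """(6, 12) strain-displacement matrix from (4, 3) shape gradients."""
    B = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = grads[i]
        c = 3 * i
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def element_stiffness(tet_coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 stiffness block V * B^T D B of one constant-strain tetrahedron."""
    tet_coords = np.asarray(tet_coords, dtype=float)
    vol, grads = _shape_gradients(tet_coords)
    if vol <= 0:
        raise SolverError(f"non-positive element volume {vol:.3e}")
    B = _b_matrix(grads)
    D = elasticity_matrix(material)
    return vol * (B.T @ D @ B)


def _batched_element_data(model: TetModel):
    p = model.nodes[model.elements]  # (ne, 4, 3)
    ne = len(p)
    M = np.ones((ne, 4, 4))
    M[:, :, 1:] = p
    vols = np.linalg.det(M) / 6.0
    if (vols <= 0).any():
        bad = np.nonzero(vols <= 0)[0][:10].tolist()
        raise SolverError(f"non-positive element volumes at {bad}")
    grads = np.transpose(np.linalg.inv(M)[:, 1:, :], (0, 2, 1))  # (ne, 4, 3)
    B = np.zeros((ne, 6, 12))
    for i in range(4):
        bx, by, bz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c] = by
        B[:, 3, c + 1] = bx
        B[:, 4, c + 1] = bz
        B[:, 4, c + 2] = by
        B[:, 5, c] = bz
        B[:, 5, c + 2] = bx
    return vols, B


def assemble(model: TetModel, material: Optional[Material] = None) -> sp.csr_matrix:
    """Assemble the global sparse symmetric stiffness matrix (3n x 3n)."""
    mat = material or model.material
    D = elasticity_matrix(mat)
    vols, B = _batched_element_data(model)
    Ke = np.einsum("e,eki,kl,elj->eij", vols, B, D, B, optimize=True)  # (ne, 12, 12)
    dofs = (3 * model.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * len(model.nodes)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def pressure_nodal_forces(
    model: TetModel, pressure_by_region: Mapping[str, float]
) -> np.ndarray:
    """Consistent nodal forces of uniform pressures on labelled boundary faces.

    Each loaded face of area A and outward unit normal n contributes
    -p * A * n / 3 to each of its three nodes (positive p pushes inward).
    """
    present = set(model.boundary_labels.tolist())
    missing = [r for r in pressure_by_region if r not in present]
    if missing:
        raise SolverError(f"load regions absent from mesh: {missing}")
    f = np.zeros((len(model.nodes), 3))
    for region, p in pressure_by_region.items():
        faces = model.faces_with_label(region)
        v = model.nodes
        an2 = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
        face_force = -p * 0.5 * an2  # p * A * n, inward
        for k in range(3):
            np.add.at(f, faces[:, k], face_force / 3.0)
    return f


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def _pick_321_nodes(nodes: np.ndarray) -> Tuple[int, int, int]:
    """Three mutually distant nodes, chosen deterministically."""
    a = int(np.lexsort((nodes[:, 2], nodes[:, 1], nodes[:, 0]))[-1])  # max x
    d = np.linalg.norm(nodes - nodes[a], axis=1)
    b = int(d.argmax())
    ab = nodes[b] - nodes[a]
    ab = ab / np.linalg.norm(ab)
    proj = nodes[a] + np.outer((nodes - nodes[a]) @ ab, ab)
    c = int(np.linalg.norm(nodes - proj, axis=1).argmax())
    return a, b, c


def minimal_321_constraints(nodes: np.ndarray) -> Dict[int, str]:
    """3-2-1 rigid-mode suppression: 3 translations at node A, 2 components
    perpendicular to AB at node B, 1 component along the ABC plane normal at
    node C."""
    a, b, c = _pick_321_nodes(nodes)
    ab = nodes[b] - nodes[a]
    axis_b = int(np.abs(ab).argmax())  # drop the component most along AB
    comps_b = "".join(ax for i, ax in enumerate("xyz") if i != axis_b)
    n = np.cross(ab, nodes[c] - nodes[a])
    axis_c = int(np.abs(n).argmax())
    return {a: "xyz", b: comps_b, c: "xyz"[axis_c]}


def _dof_indices(fixed_nodes: Mapping[int, str]) -> np.ndarray:
    idx = []
    for n, comps in sorted(fixed_nodes.items()):
        for ax in comps:
            idx.append(3 * n + "xyz".index(ax))
    return np.asarray(sorted(set(idx)), dtype=np.int64)


def _lumped_masses(model: TetModel) -> np.ndarray:
    vols = model.element_volumes()
    m = np.zeros(len(model.nodes))
    for k in range(4):
        np.add.at(m, model.elements[:, k], vols / 4.0)
    return m


def _inertia_relief_forces(model: TetModel, f: np.ndarray) -> np.ndarray:
    """Body-force field balancing the net force and moment of ``f``."""
    m = _lumped_masses(model)
    M = m.sum()
    com = (m[:, None] * model.nodes).sum(axis=0) / M
    r = model.nodes - com
    F = f.sum(axis=0)
    T = np.cross(r, f).sum(axis=0)
    # rigid inertia about the centre of mass
    I = np.zeros((3, 3))
    r2 = (r**2).sum(axis=1)
    I[np.arange(3), np.arange(3)] = (m * r2).sum()
    I -= np.einsum("n,ni,nj->ij", m, r, r)
    acc = F / M
    alpha = np.linalg.solve(I, T)
    relief = -(m[:, None] * (acc[None, :] + np.cross(alpha[None, :], r)))
    return relief


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class StaticSolver:
    """Factorizes the constrained stiffness once; solves many load cases.

    ``rigid_mode_strategy``: ``"fixed"`` uses the case's own constraints,
    ``"minimal_321"`` adds the deterministic 3-2-1 set (for self-equilibrated
    pressure cases), ``"inertia_relief"`` additionally balances any residual
    load resultant with a rigid-body inertial body force.
    """

    def __init__(self, model: TetModel, rigid_mode_strategy: str = "minimal_321",
                 fixed_nodes: Optional[Mapping[int, str]] = None):
        if rigid_mode_strategy not in ("fixed", "minimal_321", "inertia_relief"):
            raise SolverError(f"unknown rigid_mode_strategy {rigid_mode_strategy!r}")
        self.model = model
        self.strategy = rigid_mode_strategy
        if rigid_mode_strategy == "fixed":
            if not fixed_nodes:
                raise SolverError("strategy 'fixed' requires fixed_nodes")
            self.fixed_nodes = dict(fixed_nodes)
        else:
            self.fixed_nodes = minimal_321_constraints(model.nodes)
            if fixed_nodes:
                self.fixed_nodes.update(fixed_nodes)
        self.K = assemble(model)
        n = self.K.shape[0]
        fixed = _dof_indices(self.fixed_nodes)
        self.fixed_dofs = fixed
        self.free = np.setdiff1d(np.arange(n), fixed)
        Kff = self.K[self.free][:, self.free].tocsc()
        try:
            self.lu = spla.splu(Kff)
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"singular system (insufficient constraints?): {exc}") from exc
        self._vols, self._B = _batched_element_data(model)
        self._D = elasticity_matrix(model.material)

    def solve(self, case: LoadCase) -> StressField:
        case.validate()
        model = self.model
        f = np.zeros((len(model.nodes), 3))
        if case.pressure_by_region:
            f += pressure_nodal_forces(model, case.pressure_by_region)
        for n, F in case.point_loads.items():
            f[int(n)] += np.asarray(F, dtype=float)
        gross = float(np.linalg.norm(f, axis=1).sum())
        if self.strategy == "inertia_relief" and gross > 0:
            f = f + _inertia_relief_forces(model, f)
        fv = f.ravel()
        u = np.zeros_like(fv)
        u[self.free] = self.lu.solve(fv[self.free])
        if not np.all(np.isfinite(u)):
            raise SolverError("solver produced non-finite displacements")
        # residual check on free dofs
        resid = self.K @ u - fv
        rnorm = np.linalg.norm(resid[self.free])
        fnorm = np.linalg.norm(fv[self.free])
        if fnorm > 0 and rnorm > 1e-6 * fnorm:
            raise SolverError(f"solve residual too large: {rnorm:.3e} vs load {fnorm:.3e}")

        reactions = {}
        for n_, comps in self.fixed_nodes.items():
            r = np.zeros(3)
            for ax in comps:
                d = 3 * n_ + "xyz".index(ax)
                r["xyz".index(ax)] = resid[d]
            reactions[n_] = r

        ue = u.reshape(-1, 3)[model.elements].reshape(len(model.elements), 12)
        strain = np.einsum("eij,ej->ei", self._B, ue)
        stress = strain @ self._D.T
        principal = _principal_stresses(stress)
        nodal = _nodal_average_sigma1(model, principal[:, 0], self._vols)
        return StressField(
            element_stress=stress,
            principal=principal,
            nodal_max_principal=nodal,
            displacement=u.reshape(-1, 3),
            reactions=reactions,
            applied_force=f.sum(axis=0),
            gross_force=gross,
            case_name=case.name,
        )


def _principal_stresses(stress: np.ndarray) -> np.ndarray:
    """Sorted (descending) eigenvalues of the Voigt stress tensors."""
    ne = len(stress)
    T = np.empty((ne, 3, 3))
    sxx, syy, szz, sxy, syz, szx = stress.T
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = sxx, syy, szz
    T[:, 0, 1] = T[:, 1, 0] = sxy
    T[:, 1, 2] = T[:, 2, 1] = syz
    T[:, 0, 2] = T[:, 2, 0] = szx
    return np.linalg.eigvalsh(T)[:, ::-1]


def _nodal_average_sigma1(
    model: TetModel, sigma1: np.ndarray, vols: Optional[np.ndarray] = None,
    weighting: str = "volume",
) -> np.ndarray:
    """Nodal sigma_1 as the (volume-weighted by default) average of the
    adjacent elements' values."""
    if vols is None:
        vols = model.element_volumes()
    w = vols if weighting == "volume" else np.ones_like(vols)
    num = np.zeros(len(model.nodes))
    den = np.zeros(len(model.nodes))
    for k in range(4):
        np.add.at(num, model.elements[:, k], w * sigma1)
        np.add.at(den, model.elements[:, k], w)
    out = np.zeros(len(model.nodes))
    has = den > 0
    out[has] = num[has] / den[has]
    return out


def nodal_average(model: TetModel, per_element: np.ndarray,
                  weighting: str = "volume") -> np.ndarray:
    """Public nodal-averaging helper (volume-weighted or arithmetic mean)."""
    return _nodal_average_sigma1(model, per_element, None, weighting)


def solve(model: TetModel, case: LoadCase,
          rigid_mode_strategy: str = "auto") -> StressField:
    """One-shot solve; see :class:`StaticSolver` for strategies.

    ``"auto"`` uses the case's constraints when present, otherwise the
    minimal 3-2-1 set (the no-constraint pressure situation).
    """
    if rigid_mode_strategy == "auto":
        rigid_mode_strategy = "fixed" if case.fixed_nodes else "minimal_321"
    solver = StaticSolver(model, rigid_mode_strategy,
                          fixed_nodes=case.fixed_nodes or None)
    return solver.solve(case)
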