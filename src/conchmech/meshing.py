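"""Mid-surface to TET4 volumetric meshing, quality metrics and convergence.

The thin shell structures are meshed by normal-offset extrusion: every
mid-surface triangle is extruded ±t/2 along the area-weighted vertex normals
into a wedge, and each wedge is split into three tetrahedra.  The wedge
split uses the lowest-global-node-index diagonal rule, so the quadrilateral
face shared by two neighbouring wedges (or by two stacked layers) is
triangulated identically on both sides and the mesh is conforming by
construction.  Several layers through the thickness are supported; bending-
dominated validation problems need >= 2 layers of constant-strain elements.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import regions as R
from .geometry import GeometryError, SurfaceMesh


class MeshingError(ValueError):
    pass


@dataclass
class Material:
    """Isotropic linear-elastic material in the mm-N-MPa unit system."""

    young_modulus: float = 50_000.0  # MPa (nacre, 50 GPa)
    poisson_ratio: float = 0.29

    def validate(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be > 0")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (-1, 0.5)")


NACRE = Material()


@dataclass
class TetModel:
    """TET4 volumetric mesh with labelled boundary faces.

    Elements follow the positive-volume node-ordering convention
    ``det(p1-p0, p2-p0, p3-p0) > 0``.  ``boundary_faces`` are oriented
    outward (the owning element's fourth node lies behind the face).
    ``node_sets`` maps a region/tag label to the sorted node indices carrying
    it; ``node_region_map`` gives the inverse view (node -> set of labels).
    """

    nodes: np.ndarray  # (n, 3) float64, mm
    elements: np.ndarray  # (ne, 4) int64
    boundary_faces: np.ndarray  # (nf, 3) int64, outward-oriented
    boundary_labels: np.ndarray  # (nf,) unicode
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    material: Material = field(default_factory=Material)
    metadata: Dict = field(default_factory=dict)

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def node_region_map(self, node: int) -> set:
        return {lab for lab, ids in self.node_sets.items() if node in ids}

    def nodes_with_label(self, *labels: str) -> np.ndarray:
        out = [self.node_sets[lab] for lab in labels if lab in self.node_sets]
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(out))

    def faces_with_label(self, *labels: str) -> np.ndarray:
        mask = np.isin(self.boundary_labels, list(labels))
        return self.boundary_faces[mask]

    def validate(self) -> None:
        v = self.element_volumes()
        if (v <= 0).any():
            bad = np.nonzero(v <= 0)[0][:10].tolist()
            raise MeshingError(f"non-positive element volumes at {bad}")
        if self.elements.max() >= len(self.nodes):
            raise MeshingError("element node index out of range")
        ext = extract_boundary_faces(self.elements)
        a = {frozenset(f) for f in ext.tolist()}
        b = {frozenset(f) for f in self.boundary_faces.tolist()}
        if a != b:
            raise MeshingError("boundary_faces do not match single-use element faces")


# ---------------------------------------------------------------------------
# wedge split
# ---------------------------------------------------------------------------

_ROT = (1, 2, 0, 4, 5, 3)
_FLIP = (3, 5, 4, 0, 2, 1)
_TEMPLATE_A = ((0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3))  # far-quad diagonal (1,5)
_TEMPLATE_B = ((0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3))  # far-quad diagonal (2,4)


def split_wedge(prism: Sequence[int]) -> List[Tuple[int, int, int, int]]:
    """Split a wedge (bottom b0,b1,b2; top t0,t1,t2) into 3 tets.

    Diagonals of all three quad faces pass through each quad's lowest global
    node index, so adjacent wedges sharing a quad triangulate it identically.
    The bottom triangle must be wound with its normal pointing toward the top.
    """
    w = list(prism)
    pos = int(np.argmin(w))
    if pos >= 3:
        w = [w[i] for i in _FLIP]
        pos = int(np.argmin(w))
    for _ in range(pos):
        w = [w[i] for i in _ROT]
    template = _TEMPLATE_A if min(w[1], w[5]) < min(w[2], w[4]) else _TEMPLATE_B
    return [tuple(w[i] for i in tet) for tet in template]


def extract_boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Outward-oriented faces used by exactly one element."""
    f = np.concatenate([
        elements[:, [1, 2, 3]],
        elements[:, [0, 3, 2]],
        elements[:, [0, 1, 3]],
        elements[:, [0, 2, 1]],
    ])
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return f[counts[inv] == 1]


def _extrusion_normals(surface: SurfaceMesh) -> np.ndarray:
    """Per-vertex extrusion directions.

    Within one structural group (wall, septum) these are area-weighted vertex
    normals.  At junction vertices shared by several groups the groups' unit
    normals are averaged with equal weight: an area-weighted average there is
    dominated by the wall and runs almost within the septal plane, which
    would invert the septum's margin wedges.
    """
    tri = surface.triangles
    fn = surface.triangle_normals(normalize=False)  # area-weighted
    groups = np.array([R.STRUCTURE_OF.get(str(l), "wall") for l in surface.region_labels])
    nv = len(surface.vertices)
    out = np.zeros((nv, 3))
    count = np.zeros(nv)
    for g in np.unique(groups):
        sel = groups == g
        acc = np.zeros((nv, 3))
        for k in range(3):
            np.add.at(acc, tri[sel][:, k], fn[sel])
        nrm = np.linalg.norm(acc, axis=1)
        has = nrm > 0
        acc[has] /= nrm[has, None]
        out[has] += acc[has]
        count[has] += 1
    nrm = np.linalg.norm(out, axis=1)
    ok = nrm > 1e-12
    if not ok[count > 0].all():
        raise MeshingError("degenerate extrusion normal (opposing structures cancel)")
    out[ok] /= nrm[ok, None]
    # relax the direction field: junction vertices change direction sharply
    # against their one-ring, which shears the adjacent wedges into slivers
    # at strong fluting; two Jacobi passes spread the transition
    edges = np.unique(np.sort(np.concatenate(
        [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1), axis=0)
    for _ in range(2):
        acc = out.copy()
        np.add.at(acc, edges[:, 0], 0.5 * out[edges[:, 1]])
        np.add.at(acc, edges[:, 1], 0.5 * out[edges[:, 0]])
        nrm = np.linalg.norm(acc, axis=1)
        good = nrm > 1e-12
        out[good] = acc[good] / nrm[good, None]
    return out


def extrude_to_tets(
    surface: SurfaceMesh,
    thickness: Union[float, Dict[str, float]],
    n_layers: int = 1,
    material: Optional[Material] = None,
) -> TetModel:
    """Extrude a labelled mid-surface into a TET4 model.

    ``thickness`` is either a scalar (mm) or a mapping region label ->
    thickness; per-vertex offsets then use the area-weighted mean of the
    incident triangles' thicknesses, which blends wall and septum thickness
    smoothly across their junctions.  Offsetting must not fold the surface:
    if any offset triangle's normal flips against its mid-surface normal
    (thickness too large for the local curvature) the offending triangles are
    reported and the extrusion rejected.
    """
    if n_layers < 1:
        raise MeshingError("n_layers must be >= 1")
    tri = surface.triangles
    nv = len(surface.vertices)

    if isinstance(thickness, dict):
        t_tri = np.array([thickness[lab] for lab in surface.region_labels], dtype=float)
    else:
        t_tri = np.full(len(tri), float(thickness))
    if (t_tri <= 0).any():
        raise MeshingError("thickness must be > 0")

    areas = surface.triangle_areas()
    wsum = np.zeros(nv)
    tsum = np.zeros(nv)
    for k in range(3):
        np.add.at(wsum, tri[:, k], areas)
        np.add.at(tsum, tri[:, k], areas * t_tri)
    used = wsum > 0
    t_v = np.zeros(nv)
    t_v[used] = tsum[used] / wsum[used]

    normals = _extrusion_normals(surface)
    offsets = normals * t_v[:, None]

    # fold check at the extreme offsets
    fn = surface.triangle_normals()
    for s in (-0.5, 0.5):
        v_off = surface.vertices + s * offsets
        n_off = np.cross(v_off[tri[:, 1]] - v_off[tri[:, 0]], v_off[tri[:, 2]] - v_off[tri[:, 0]])
        bad = np.nonzero(np.einsum("ij,ij->i", n_off, fn) <= 0)[0]
        if len(bad):
            raise MeshingError(
                "offset surface self-intersects (thickness exceeds local curvature "
                f"radius) at triangles {bad[:20].tolist()}"
            )

    layers = [
        surface.vertices + (l / n_layers - 0.5) * offsets for l in range(n_layers + 1)
    ]
    nodes = np.concatenate(layers, axis=0)

    elems: List[Tuple[int, int, int, int]] = []
    elem_tri: List[int] = []
    for l in range(n_layers):
        lo, hi = l * nv, (l + 1) * nv
        for ti, (i0, i1, i2) in enumerate(tri):
            prism = (lo + i0, lo + i1, lo + i2, hi + i0, hi + i1, hi + i2)
            for tet in split_wedge(prism):
                elems.append(tet)
                elem_tri.append(ti)
    elements = np.asarray(elems, dtype=np.int64)

    vols = np.linalg.det(nodes[elements][:, 1:] - nodes[elements][:, :1]) / 6.0
    if (vols <= 0).any():
        bad = np.unique(np.asarray(elem_tri)[vols <= 0])
        raise MeshingError(f"degenerate extrusion at triangles {bad[:20].tolist()}")

    faces = extract_boundary_faces(elements)

    # classify boundary faces: all-top -> outer, all-bottom -> inner, else rim
    top_off, bot_hi = n_layers * nv, nv
    tri_of = {frozenset(t): i for i, t in enumerate(tri.tolist())}
    labels = np.empty(len(faces), dtype=object)
    for i, f in enumerate(faces):
        if (f >= top_off).all():
            lab = surface.region_labels[tri_of[frozenset((f - top_off).tolist())]]
            labels[i] = R.OUTER_FACE_LABEL[str(lab)]
        elif (f < bot_hi).all():
            lab = surface.region_labels[tri_of[frozenset(f.tolist())]]
            labels[i] = R.INNER_FACE_LABEL[str(lab)]
        else:
            labels[i] = R.EDGE_RIM
    labels = labels.astype(str)

    # node sets: from face labels, plus surface vertex tags on every layer copy
    node_sets: Dict[str, List[int]] = {}
    for lab in np.unique(labels):
        sel = labels == lab
        node_sets[str(lab)] = np.unique(faces[sel]).tolist()
    for tag, vids in surface.vertex_tags.items():
        copies = np.concatenate([vids + l * nv for l in range(n_layers + 1)])
        node_sets.setdefault(tag, [])
        node_sets[tag] = np.unique(np.concatenate([np.asarray(node_sets[tag], dtype=np.int64), copies])).tolist()

    model = TetModel(
        nodes=nodes,
        elements=elements,
        boundary_faces=faces,
        boundary_labels=labels,
        node_sets={k: np.asarray(sorted(v), dtype=np.int64) for k, v in node_sets.items()},
        material=material or Material(),
        metadata=dict(surface.metadata, n_layers=n_layers, mid_vertices=nv),
    )
    return model


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def decimate(surface: SurfaceMesh, factor: int) -> SurfaceMesh:
    """Edge-collapse decimation targeting ``triangle_count / factor**2``.

    Deterministic shortest-edge-first midpoint collapses with a link-condition
    check (no non-manifold pinches) and a normal-flip guard; collapses that
    would break these stop early and the achieved count stands.  Region
    labels ride along on the surviving triangles.  Factor 1 is the identity.
    """
    if factor not in (1, 2, 4, 6):
        raise MeshingError("factor must be one of {1, 2, 4, 6}")
    if factor == 1:
        return SurfaceMesh(
            surface.vertices.copy(), surface.triangles.copy(),
            surface.region_labels.copy(),
            {k: v.copy() for k, v in surface.vertex_tags.items()},
            dict(surface.metadata),
        )
    target = max(4, int(round(len(surface.triangles) / factor**2)))

    verts = [tuple(v) for v in surface.vertices]
    tris: Dict[int, Tuple[int, int, int]] = {i: tuple(t) for i, t in enumerate(surface.triangles.tolist())}
    labels: Dict[int, str] = {i: str(l) for i, l in enumerate(surface.region_labels)}
    v2t: Dict[int, set] = {}
    for ti, t in tris.items():
        for v in t:
            v2t.setdefault(v, set()).add(ti)

    alive_v = set(v2t)
    pos = {v: np.asarray(verts[v]) for v in alive_v}

    def edge_len(a: int, b: int) -> float:
        return float(np.linalg.norm(pos[a] - pos[b]))

    def edges_of(ti: int):
        a, b, c = tris[ti]
        return ((a, b), (b, c), (c, a))

    heap: List[Tuple[float, int, int]] = []
    seen = set()
    for ti in tris:
        for a, b in edges_of(ti):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                heapq.heappush(heap, (edge_len(*key), *key))

    boundary_v = set()
    ecount: Dict[Tuple[int, int], int] = {}
    for ti in tris:
        for a, b in edges_of(ti):
            key = (min(a, b), max(a, b))
            ecount[key] = ecount.get(key, 0) + 1
    for (a, b), c in ecount.items():
        if c == 1:
            boundary_v.update((a, b))

    def neighbors(v: int) -> set:
        out = set()
        for ti in v2t.get(v, ()):  # noqa: B905
            out.update(tris[ti])
        out.discard(v)
        return out

    ntri = len(tris)
    while ntri > target and heap:
        _, a, b = heapq.heappop(heap)
        if a not in alive_v or b not in alive_v:
            continue
        shared = v2t[a] & v2t[b]
        if not shared or len(shared) != 2:
            continue  # boundary or stale edge
        if a in boundary_v or b in boundary_v:
            continue
        # link condition
        link = neighbors(a) & neighbors(b)
        opp = set()
        for ti in shared:
            opp.update(set(tris[ti]) - {a, b})
        if link != opp:
            continue
        mid = 0.5 * (pos[a] + pos[b])
        # flip guard on surviving triangles around a and b
        affected = (v2t[a] | v2t[b]) - shared
        ok = True
        for ti in affected:
            t = tris[ti]
            p = [pos[v] if v not in (a, b) else None for v in t]
            old = np.cross(pos[t[1]] - pos[t[0]], pos[t[2]] - pos[t[0]])
            q = [mid if v in (a, b) else pos[v] for v in t]
            new = np.cross(q[1] - q[0], q[2] - q[0])
            if float(old @ new) <= 0 or float(np.linalg.norm(new)) < 1e-12:
                ok = False
                break
        if not ok:
            continue
        # commit: b merges into a
        pos[a] = mid
        for ti in shared:
            for v in tris[ti]:
                v2t[v].discard(ti)
            del tris[ti], labels[ti]
            ntri -= 1
        for ti in list(v2t.get(b, ())):
            t = tris[ti]
            tris[ti] = tuple(a if v == b else v for v in t)
            v2t[a].add(ti)
            v2t[b].discard(ti)
        alive_v.discard(b)
        for n in neighbors(a):
            heapq.heappush(heap, (edge_len(a, n), min(a, n), max(a, n)))

    # compact
    order = sorted(tris)
    new_tris = np.asarray([tris[i] for i in order], dtype=np.int64)
    new_labels = np.asarray([labels[i] for i in order])
    used = np.unique(new_tris)
    remap = -np.ones(len(surface.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_verts = np.asarray([pos.get(v, np.asarray(verts[v])) for v in used])
    out = SurfaceMesh(new_verts, remap[new_tris], new_labels)
    out.metadata = dict(surface.metadata, decimation_factor=factor,
                        achieved_triangles=int(ntri), target_triangles=int(target))
    tags = {}
    for k, vids in surface.vertex_tags.items():
        kept = remap[vids]
        tags[k] = np.asarray(sorted(kept[kept >= 0]), dtype=np.int64)
    out.vertex_tags = tags
    return out


# ---------------------------------------------------------------------------
# quality and convergence
# ---------------------------------------------------------------------------

@dataclass
class MeshQualityReport:
    aspect_ratio: np.ndarray  # per element, >= 1, 1 for the regular tet
    min_dihedral_deg: np.ndarray
    max_dihedral_deg: np.ndarray
    element_count: int
    node_count: int

    def summary(self) -> Dict[str, float]:
        return {
            "elements": self.element_count,
            "nodes": self.node_count,
            "aspect_mean": float(self.aspect_ratio.mean()),
            "aspect_max": float(self.aspect_ratio.max()),
            "dihedral_min": float(self.min_dihedral_deg.min()),
            "dihedral_max": float(self.max_dihedral_deg.max()),
        }


_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
_EDGE_FACES = (  # tet edge -> the two adjacent faces (indices into _FACES)
    ((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)),
    ((1, 2), (0, 3)), ((1, 3), (0, 2)), ((2, 3), (0, 1)),
)


def mesh_quality(model: TetModel) -> MeshQualityReport:
    """Per-element aspect ratio (longest edge / (2*sqrt(6) * inradius)) and
    dihedral angle extrema."""
    if len(model.elements) == 0:
        raise MeshingError("empty model")
    p = model.nodes[model.elements]  # (ne, 4, 3)
    edges = np.stack([p[:, b] - p[:, a] for (a, b), _ in _EDGE_FACES], axis=1)
    elens = np.linalg.norm(edges, axis=2)
    longest = elens.max(axis=1)

    vols = np.abs(np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0)
    face_areas = np.stack(
        [0.5 * np.linalg.norm(np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]]), axis=1)
         for f in _FACES], axis=1)
    inradius = 3.0 * vols / face_areas.sum(axis=1)
    aspect = longest / (2.0 * np.sqrt(6.0) * inradius)

    fnorm = np.stack(
        [np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]]) for f in _FACES], axis=1)
    fnorm = fnorm / np.linalg.norm(fnorm, axis=2, keepdims=True)
    dihedrals = []
    for _, (fa, fb) in _EDGE_FACES:
        cosang = -np.einsum("ij,ij->i", fnorm[:, fa], fnorm[:, fb])
        dihedrals.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    dihedrals = np.stack(dihedrals, axis=1)

    return MeshQualityReport(
        aspect_ratio=aspect,
        min_dihedral_deg=dihedrals.min(axis=1),
        max_dihedral_deg=dihedrals.max(axis=1),
        element_count=len(model.elements),
        node_count=len(model.nodes),
    )


def convergence_check(
    results: Sequence[Tuple[float, float]], tol: float = 0.10
) -> Tuple[bool, Optional[int]]:
    """Apply the 10%-peak-stress convergence criterion to a refinement ladder.

    ``results`` is ordered coarse -> fine as ``(mesh_size, peak_stress)``.
    Converged when the two finest peaks differ by <= ``tol`` relative to the
    finer; the chosen level is the coarsest whose peak is within ``tol`` of
    the finest (and of every finer level after it).
    """
    if len(results) < 2:
        raise MeshingError("convergence check requires >= 2 refinement levels")
    peaks = [p for _, p in results]
    fin = peaks[-1]
    if fin == 0:
        raise MeshingError("finest peak stress is zero")
    converged = abs(peaks[-1] - peaks[-2]) / abs(peaks[-1]) <= tol
    chosen: Optional[int] = None
    if converged:
        for i in range(len(peaks) - 1):
            if all(abs(peaks[j] - fin) / abs(fin) <= tol for j in range(i, len(peaks))):
                chosen = i
                break
        if chosen is None:
            chosen = len(peaks) - 1
    return converged, chosen
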