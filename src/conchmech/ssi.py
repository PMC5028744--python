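"""Septal strength index (SSI) and implosion-depth approximation.

SSI = 1000 * delta / R, where delta is the minimum septal thickness and R a
radius of curvature of the septal section, both in mm.  Depth is approximated
as a fixed conversion of SSI (30.0 m per SSI unit, the ratio implied by the
published depth tables).  The index is known to be unstable: R depends
strongly on where along the section the three curvature sample points are
placed, especially on fluted septa.  :func:`ssi_sampling_spread` quantifies
that spread instead of hiding it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import regions as R
from .meshing import TetModel
from .postprocess import FINAL_SEPTUM_LABELS

#: metres of implosion depth per SSI unit
DEPTH_PER_SSI = 30.0


class SSIError(ValueError):
    pass


@dataclass
class SSIMeasurement:
    thickness: float  # delta, mm
    radius_of_curvature: float  # R, mm
    ssi: float
    depth: float  # m
    section: str = "median"  # median | transverse


def circle_from_three_points(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]
) -> Tuple[np.ndarray, float]:
    """Circumscribed circle of three non-collinear 2D points."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    c = np.asarray(p3, dtype=float)
    area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if abs(area2) < 2e-12:
        raise SSIError("points are collinear (no finite circumscribed circle)")
    sa, sb, sc = (a**2).sum(), (b**2).sum(), (c**2).sum()
    ux = (sa * (b[1] - c[1]) + sb * (c[1] - a[1]) + sc * (a[1] - b[1])) / (2 * area2)
    uy = (sa * (c[0] - b[0]) + sb * (a[0] - c[0]) + sc * (b[0] - a[0])) / (2 * area2)
    centre = np.array([ux, uy])
    return centre, float(np.linalg.norm(a - centre))


def compute_ssi(thickness: float, radius_of_curvature: float) -> float:
    """SSI = 1000 * delta / R."""
    if thickness <= 0 or radius_of_curvature <= 0:
        raise SSIError("thickness and radius of curvature must be > 0")
    return 1000.0 * thickness / radius_of_curvature


def depth_from_ssi(ssi, conversion: float = DEPTH_PER_SSI):
    """Approximate implosion depth in metres (scalar or array)."""
    if np.any(np.asarray(ssi) < 0):
        raise SSIError("ssi must be >= 0")
    return conversion * ssi


# ---------------------------------------------------------------------------
# section measurement on a TetModel
# ---------------------------------------------------------------------------

def _plane_basis(normal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n, e1)


def _section_polylines(faces: np.ndarray, nodes: np.ndarray,
                       origin: np.ndarray, normal: np.ndarray) -> List[np.ndarray]:
    """Intersect a triangulated face set with a plane; chain into polylines."""
    import trimesh

    used = np.unique(faces)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(len(used))
    tm = trimesh.Trimesh(vertices=nodes[used], faces=remap[faces], process=False)
    segments = trimesh.intersections.mesh_plane(tm, plane_normal=normal,
                                                plane_origin=origin)
    if segments is None or len(segments) == 0:
        return []
    return _chain_segments(np.asarray(segments))


def _chain_segments(segments: np.ndarray, tol: float = 1e-7) -> List[np.ndarray]:
    """Join (n, 2, 3) unordered segments into ordered polylines."""

    def key(p):
        return tuple(np.round(p / tol).astype(np.int64))

    # adjacency: endpoint key -> list of (segment index, end index)
    adj: dict = {}
    for i, seg in enumerate(segments):
        for e in (0, 1):
            adj.setdefault(key(seg[e]), []).append((i, e))

    unused = set(range(len(segments)))
    polys = []
    while unused:
        i = min(unused)
        unused.discard(i)
        chain = [segments[i][0], segments[i][1]]
        # extend forward then backward
        for direction in (1, 0):
            while True:
                end = chain[-1] if direction else chain[0]
                nxt = None
                for j, e in adj.get(key(end), []):
                    if j in unused:
                        nxt = (j, e)
                        break
                if nxt is None:
                    break
                j, e = nxt
                unused.discard(j)
                other = segments[j][1 - e]
                if direction:
                    chain.append(other)
                else:
                    chain.insert(0, other)
        polys.append(np.asarray(chain))
    return polys


def _to_2d(poly: np.ndarray, origin: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    rel = poly - origin
    return np.stack([rel @ e1, rel @ e2], axis=1)


def _resample(poly: np.ndarray, n: int = 200) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return poly[:1].repeat(n, axis=0)
    t = np.linspace(0, s[-1], n)
    out = np.empty((n, poly.shape[1]))
    for k in range(poly.shape[1]):
        out[:, k] = np.interp(t, s, poly[:, k])
    return out


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum distance from points ``a`` to the polyline ``b`` (segments)."""
    p0, p1 = b[:-1], b[1:]
    d = p1 - p0
    L2 = (d**2).sum(axis=1)
    L2[L2 == 0] = 1.0
    rel = a[:, None, :] - p0[None, :, :]
    t = np.clip((rel * d[None, :, :]).sum(axis=2) / L2[None, :], 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    return float(np.linalg.norm(a[:, None, :] - proj, axis=2).min())


def measure_septum_section(
    model: TetModel,
    plane_origin: Sequence[float] = (0.0, 0.0, 0.0),
    plane_normal: Sequence[float] = (0.0, 0.0, 1.0),
    placements: Sequence[float] = (0.25, 0.5, 0.75),
    section_kind: str = "median",
) -> SSIMeasurement:
    """Measure delta and R on a planar section of the final septum.

    The plane (default: the median plane z = 0) cuts the septum's adoral and
    adapical face meshes into section polylines.  delta is the minimum
    distance between the two curves; R is the circumscribed-circle radius of
    three points at the given arc-length fractions of the mid-curve (25%,
    50%, 75% by default, emulating manual three-point placement).
    """
    origin = np.asarray(plane_origin, dtype=float)
    normal = np.asarray(plane_normal, dtype=float)
    adoral = model.faces_with_label(R.FINAL_SEPTUM_ADAPERTURAL)
    adapical = model.faces_with_label(R.FINAL_SEPTUM_ADAPICAL)
    if len(adoral) == 0 or len(adapical) == 0:
        raise SSIError("model lacks labelled final-septum faces")
    pa = _section_polylines(adoral, model.nodes, origin, normal)
    pb = _section_polylines(adapical, model.nodes, origin, normal)
    if not pa or not pb:
        raise SSIError("section plane misses the final septum")
    # the plane cuts the annular septum into limbs on each side of the
    # foramen; pair the adoral and adapical limbs that actually face each
    # other (closest centroids), preferring the longest adoral limb
    def length(p):
        return np.linalg.norm(np.diff(p, axis=0), axis=1).sum()

    pa = max(pa, key=length)
    ca = pa.mean(axis=0)
    pb = min(pb, key=lambda p: np.linalg.norm(p.mean(axis=0) - ca))

    e1, e2 = _plane_basis(normal)
    a2 = _resample(_to_2d(pa, origin, e1, e2))
    b2 = _resample(_to_2d(pb, origin, e1, e2))
    # align traversal directions
    if np.linalg.norm(a2[0] - b2[0]) > np.linalg.norm(a2[0] - b2[-1]):
        b2 = b2[::-1]

    # trim the curve ends before measuring delta: near the suture junction the
    # septum blends into the wall (the offset faces rotate toward the junction
    # bisector) and near the foramen the free rim connects the faces; neither
    # zone is septal plate thickness
    trim = max(1, int(0.15 * len(a2)))
    thickness = _min_distance(a2[trim:-trim], b2)
    mid = 0.5 * (a2 + b2)
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise SSIError("degenerate septum section")
    pts = []
    for f in placements:
        pts.append(mid[int(np.argmin(np.abs(s - f * total)))])
    try:
        _, radius = circle_from_three_points(*pts)
    except SSIError as exc:
        raise SSIError(f"curvature sample points collinear: {exc}") from exc
    ssi = compute_ssi(thickness, radius)
    return SSIMeasurement(
        thickness=thickness,
        radius_of_curvature=radius,
        ssi=ssi,
        depth=depth_from_ssi(ssi),
        section=section_kind,
    )


def ssi_sampling_spread(
    model: TetModel,
    plane_origin: Sequence[float] = (0.0, 0.0, 0.0),
    plane_normal: Sequence[float] = (0.0, 0.0, 1.0),
    n_draws: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """SSI values under randomized curvature sample-point placements.

    Draws placements uniformly (sorted triples in (0.1, 0.9) with minimum
    separation 0.15) and returns the resulting SSI values; their spread is
    the index's documented sampling instability.
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_draws:
        tri = np.sort(rng.uniform(0.1, 0.9, size=3))
        if np.min(np.diff(tri)) < 0.15:
            continue
        try:
            m = measure_septum_section(model, plane_origin, plane_normal, tri)
        except SSIError:
            continue
        out.append(m.ssi)
    return np.asarray(out)
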