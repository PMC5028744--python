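"""The comparative experimental design: hydrostatic pressure and bite loads.

Hydrostatic cases load the three wetted regions — the exterior shell wall,
the interior surface of the body chamber and the adapertural face of the
final septum — with a uniform pressure and no user constraints (the solver's
3-2-1 set carries near-zero reactions).  Point-load cases emulate bites: a
single-node force on the flank, either on the chamber wall mid-way between
the last two septa or on the suture of the penultimate septum, with the
diametrically opposite flank patch fully fixed.  Point forces are scaled to
the total surface area of each model so specimens of different size can be
compared shape-to-shape.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import regions as R
from .fea_solver import LoadCase, StaticSolver, StressField, solve
from .meshing import TetModel


class CaseError(ValueError):
    pass


@dataclass
class ExperimentSpec:
    """One row of the experimental design."""

    model_id: str
    kind: str  # hydrostatic | pressure_series | point_chamber | point_suture
    pressure: float = 0.0  # MPa
    reference_force: float = 0.0  # N
    reference_area: float = 0.0  # mm^2
    scaled_force: float = 0.0  # N


DEFAULT_PRESSURE = 8.0  # MPa, ~785 m water depth
PRESSURE_SERIES = (2.0, 4.0, 6.0, 8.0)  # MPa


def hydrostatic_case(model: TetModel, pressure: float) -> LoadCase:
    """Uniform pressure on exactly the three wetted regions; no constraints.

    Interior chamber faces other than the final septum's adapertural side
    carry no load (the <0.1 MPa chamber gas pressure is ignored).
    """
    present = set(model.boundary_labels.tolist())
    missing = [r for r in R.HYDROSTATIC_REGIONS if r not in present]
    if missing:
        raise CaseError(f"model lacks hydrostatic regions: {missing}")
    return LoadCase(
        pressure_by_region={r: float(pressure) for r in R.HYDROSTATIC_REGIONS},
        name=f"hydrostatic_{pressure:g}MPa",
    )


def pressure_series(
    model: TetModel,
    pressures: Sequence[float] = PRESSURE_SERIES,
    solver: Optional[StaticSolver] = None,
) -> List[StressField]:
    """Solve the hydrostatic case at each pressure (one factorization).

    In a linear model the fields must scale proportionally with pressure;
    this is checked and a violation raises.
    """
    if len(pressures) == 0:
        raise CaseError("empty pressure list")
    solver = solver or StaticSolver(model, "minimal_321")
    fields = [solver.solve(hydrostatic_case(model, p)) for p in pressures]
    if len(fields) > 1:
        ref_p, ref = pressures[0], fields[0]
        for p, fld in zip(pressures[1:], fields[1:]):
            scale = p / ref_p
            denom = np.abs(ref.nodal_max_principal).max()
            dev = np.abs(fld.nodal_max_principal - scale * ref.nodal_max_principal).max()
            if denom > 0 and dev > 1e-6 * scale * denom:
                raise CaseError(f"linearity violated at {p} MPa: dev {dev:.3e}")
    return fields


def scale_point_force(reference_force: float, reference_area: float, area: float) -> float:
    """Scale a point force to a model's total surface area (2 decimals)."""
    if reference_area <= 0 or area <= 0:
        raise CaseError("areas must be > 0")
    return round(reference_force * area / reference_area, 2)


def _outward_node_normals(model: TetModel, labels: Sequence[str]) -> Dict[int, np.ndarray]:
    faces = model.faces_with_label(*labels)
    v = model.nodes
    n = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    acc: Dict[int, np.ndarray] = {}
    for tri, nn in zip(faces, n):
        for node in tri:
            acc.setdefault(int(node), np.zeros(3))
            acc[int(node)] += nn
    return {k: v_ / np.linalg.norm(v_) for k, v_ in acc.items() if np.linalg.norm(v_) > 0}


def _shell_info(model: TetModel) -> Tuple[np.ndarray, float, float]:
    meta = model.metadata
    if "septum_angles" not in meta:
        raise CaseError("model does not carry shell metadata (septum stations)")
    params = meta["params"]
    return (np.asarray(meta["septum_angles"]), params["initial_radius"],
            params["whorl_expansion_rate"])


def _suture_flank_node(model: TetModel, septum_index: int, band: np.ndarray) -> int:
    """Suture node on the loaded flank (z > 0).

    The load targets the flank midline (the top of the whorl section), the
    same azimuthal position as the chamber-wall load, so the two bite
    scenarios differ only in their position along the spiral — a controlled
    comparison.  The node is resolved exactly from the ring-index arithmetic
    of the generator when available, else geometrically.
    """
    meta = model.metadata
    S = meta.get("ring_segments")
    nv = meta.get("mid_vertices")
    stations_r = meta.get("station_rings")
    if S and nv and stations_r is not None:
        k_star = int(round(S / 4.0)) % S  # phi = pi/2
        vid = stations_r[septum_index] * S + k_star
        n_layers = meta.get("n_layers", 1)
        node = n_layers * nv + vid  # outer-surface copy
        if node in band:
            return int(node)
    # geometric fallback: band node highest on the z > 0 flank
    flank = band[model.nodes[band, 2] > 0]
    if len(flank) == 0:
        flank = band
    return int(flank[int(np.argmax(model.nodes[flank, 2]))])


def point_load_case(
    model: TetModel,
    location: str,
    force: float,
    cap_half_angle_deg: float = 10.0,
) -> LoadCase:
    """Single-node bite load on the loaded flank (z > 0), antipodal patch fixed.

    ``location = "chamber_wall"``: the external-wall node nearest the flank
    point mid-way (in spiral angle) between the last two septa.
    ``location = "suture"``: the flank-most node of the penultimate septum's
    suture band.  The force acts along the inward surface normal at the
    chosen node; all external-wall nodes within the antipodal patch (mirror
    image through the coiling plane, radius set by the cap half-angle) are
    fixed in x, y and z — a single fixed node could not restrain rotation.
    """
    if location not in ("chamber_wall", "suture"):
        raise CaseError(f"unknown point-load location {location!r}")
    stations, r0, w = _shell_info(model)
    if len(stations) < 2:
        raise CaseError("point load cases need >= 2 septa")

    normals = _outward_node_normals(model, [R.EXTERNAL_WALL])
    wall_nodes = np.asarray(sorted(normals), dtype=np.int64)
    pos = model.nodes[wall_nodes]

    sec_frac = 0.38  # SECTION_FRACTION of the generator
    aspect = model.metadata["params"]["cross_section_aspect"]

    def flank_point(theta: float) -> np.ndarray:
        """Analytic flank-midline point (top of the whorl section, z > 0)."""
        Rt = r0 * np.exp(w * theta)
        half_w = sec_frac * Rt / aspect
        return np.array([Rt * np.cos(theta), Rt * np.sin(theta), half_w])

    if location == "chamber_wall":
        theta_t = 0.5 * (stations[-1] + stations[-2])
        target = flank_point(theta_t)
        cand = wall_nodes[pos[:, 2] > 0]
        node = int(cand[int(np.argmin(
            np.linalg.norm(model.nodes[cand] - target, axis=1)))])
    else:
        j = len(stations) - 2
        key = f"suture_band_{j}"
        if key not in model.node_sets:
            raise CaseError(f"model lacks {key} labels")
        band = model.node_sets[key]
        band = band[np.isin(band, wall_nodes)]
        if len(band) == 0:
            raise CaseError("no suture-band nodes on the external wall")
        node = _suture_flank_node(model, j, band)

    n_hat = normals[node]
    load_point = model.nodes[node]

    # antipodal patch: mirror through the coiling plane
    anti = load_point * np.array([1.0, 1.0, -1.0])
    local_size = sec_frac * np.linalg.norm(load_point[:2])
    radius = max(2.0 * local_size * np.sin(np.radians(cap_half_angle_deg)),
                 1e-6)
    fixed: Dict[int, str] = {}
    grow = 1.0
    while True:
        d = np.linalg.norm(model.nodes[wall_nodes] - anti, axis=1)
        sel = wall_nodes[(d <= radius * grow) & (model.nodes[wall_nodes, 2] < 0)]
        if len(sel) >= 6 or grow > 8:
            break
        grow *= 1.5
    for nn_ in sel:
        fixed[int(nn_)] = "xyz"
    if not fixed:
        raise CaseError("could not build the antipodal constraint patch")

    return LoadCase(
        point_loads={node: -float(force) * n_hat},
        fixed_nodes=fixed,
        name=f"point_{location}_{force:g}N",
    )


def run_point_load(model: TetModel, location: str, force: float,
                   cap_half_angle_deg: float = 10.0) -> StressField:
    case = point_load_case(model, location, force, cap_half_angle_deg)
    return solve(model, case, "fixed")
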