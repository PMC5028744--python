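"""File I/O: STL (+ JSON label sidecar), legacy-ASCII VTK, CSV reports.

STL carries no attribute channel, so region labels travel in a JSON sidecar
mapping triangle index ranges to labels.  Volumetric results are written as
legacy ASCII VTK unstructured grids (TET4 cells) with point data
(displacement, nodal sigma_1) and cell data (stress tensor, principal
stresses), readable by ParaView and meshio alike.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np

from .fea_solver import StressField
from .geometry import SurfaceMesh
from .meshing import TetModel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# STL + sidecar
# ---------------------------------------------------------------------------

def write_stl(surface: SurfaceMesh, path: PathLike, ascii_format: bool = False,
              sidecar: bool = True) -> Path:
    """Write a surface as STL with a JSON region-label sidecar."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=surface.vertices, faces=surface.triangles,
                         process=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm.export(path, file_type="stl_ascii" if ascii_format else "stl")
    if sidecar:
        side = path.with_suffix(path.suffix + ".labels.json")
        side.write_text(json.dumps({
            "labels": surface.region_labels.tolist(),
            "vertex_tags": {k: v.tolist() for k, v in surface.vertex_tags.items()},
            "metadata": _jsonable(surface.metadata),
        }))
    return path


def read_stl(path: PathLike) -> SurfaceMesh:
    """Read an STL (+ sidecar when present) back into a SurfaceMesh."""
    import trimesh

    path = Path(path)
    tm = trimesh.load_mesh(path, process=False)
    labels = np.full(len(tm.faces), "validation")
    tags: Dict[str, np.ndarray] = {}
    meta: Dict = {}
    side = path.with_suffix(path.suffix + ".labels.json")
    if side.exists():
        data = json.loads(side.read_text())
        labels = np.asarray(data["labels"])
        tags = {k: np.asarray(v, dtype=np.int64) for k, v in data.get("vertex_tags", {}).items()}
        meta = data.get("metadata", {})
    mesh = SurfaceMesh(np.asarray(tm.vertices, dtype=np.float64),
                       np.asarray(tm.faces, dtype=np.int64), labels, tags, meta)
    return mesh


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# VTK legacy writer
# ---------------------------------------------------------------------------

def write_vtk(
    model: TetModel,
    path: PathLike,
    field: Optional[StressField] = None,
    point_data: Optional[Mapping[str, np.ndarray]] = None,
    cell_data: Optional[Mapping[str, np.ndarray]] = None,
) -> Path:
    """Write a TET4 model (optionally with a solution) as legacy ASCII VTK."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd_: Dict[str, np.ndarray] = dict(point_data or {})
    cd: Dict[str, np.ndarray] = dict(cell_data or {})
    if field is not None:
        pd_.setdefault("displacement", field.displacement)
        pd_.setdefault("nodal_sigma1", field.nodal_max_principal)
        cd.setdefault("stress_voigt", field.element_stress)
        cd.setdefault("principal_stress", field.principal)

    lines = [
        "# vtk DataFile Version 3.0",
        "conchmech TET4 model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(model.nodes)} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in model.nodes]
    ne = len(model.elements)
    lines.append(f"CELLS {ne} {5 * ne}")
    lines += ["4 " + " ".join(str(i) for i in e) for e in model.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += ["10"] * ne  # VTK_TETRA

    def _emit(data: Mapping[str, np.ndarray], kind: str, count: int):
        if not data:
            return
        lines.append(f"{kind} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            elif arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{x:.9g}" for x in row) for row in arr)
            else:
                lines.append(f"FIELD {name}_field 1")
                lines.append(f"{name} {arr.shape[1]} {arr.shape[0]} double")
                lines.extend(" ".join(f"{x:.9g}" for x in row) for row in arr)

    _emit(pd_, "POINT_DATA", len(model.nodes))
    _emit(cd, "CELL_DATA", ne)
    path.write_text("\n".join(lines) + "\n")
    return path
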