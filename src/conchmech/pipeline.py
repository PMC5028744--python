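"""End-to-end orchestration: generate -> mesh -> solve -> summarize.

A :class:`RunConfig` (constructed directly or parsed from YAML) names a shell
preset or explicit parameters, optional mesh-refinement levels for the
convergence protocol, and the load cases to run.  ``run_experiment`` executes
the pipeline deterministically, writing STL/VTK/CSV artifacts plus a
serialized copy of the configuration and a log of mesh sizes, solver
strategy, reaction norms and case summaries.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import regions as R
from .fea_solver import LoadCase, StaticSolver, StressField, solve
from .geometry import (GeometryError, ShellParams, SurfaceMesh,
                       generate_planispiral_shell, generate_sphere_midsurface, preset)
from .io import write_stl, write_vtk
from .load_cases import (DEFAULT_PRESSURE, PRESSURE_SERIES, hydrostatic_case,
                         point_load_case, pressure_series, scale_point_force)
from .meshing import Material, TetModel, convergence_check, extrude_to_tets, mesh_quality
from .postprocess import CaseSummary, compare_table, summarize_case
from .published import reproduce_reference_arithmetic

log = logging.getLogger(__name__)

WALL_REGIONS = (R.EXTERNAL_WALL, R.BODY_CHAMBER_INTERIOR, R.SUTURE_BAND)
SEPTUM_REGIONS = (R.FINAL_SEPTUM_ADAPERTURAL, R.SEPTUM_INTERNAL, R.FORAMEN_RIM)


def region_thickness(params: ShellParams) -> Dict[str, float]:
    th = {r: params.wall_thickness for r in WALL_REGIONS}
    th.update({r: params.septum_thickness for r in SEPTUM_REGIONS})
    return th


def build_shell_model(params: ShellParams, n_layers: int = 1,
                      material: Optional[Material] = None) -> TetModel:
    """Generate a shell surface and extrude it into a TET4 model."""
    surface = generate_planispiral_shell(params)
    return extrude_to_tets(surface, region_thickness(params), n_layers=n_layers,
                           material=material)


@dataclass
class RunConfig:
    preset_name: Optional[str] = None
    params: Optional[ShellParams] = None
    cases: List[Dict] = dfield(default_factory=lambda: [{"kind": "hydrostatic",
                                                         "pressure": DEFAULT_PRESSURE}])
    mesh_levels: List[float] = dfield(default_factory=list)  # rings_per_whorl multipliers
    out_dir: Union[str, Path] = "conchmech_out"
    seed: int = 0
    solver_strategy: str = "minimal_321"
    n_layers: int = 1

    def resolve_params(self) -> ShellParams:
        if self.params is not None:
            p = self.params
        elif self.preset_name:
            p = preset(self.preset_name)
        else:
            raise ValueError("config needs preset_name or explicit params")
        p = dataclasses.replace(p, seed=self.seed)
        p.validate()
        return p

    def validate(self) -> None:
        if not self.cases:
            raise ValueError("config lists no load cases")
        for c in self.cases:
            if c.get("kind") not in ("hydrostatic", "pressure_series",
                                     "point_chamber", "point_suture"):
                raise ValueError(f"unknown case kind {c.get('kind')!r}")
        self.resolve_params()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        params = None
        if "params" in data:
            params = ShellParams(**data.pop("params"))
        return cls(params=params, **data)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _case_fields(model: TetModel, cfg: RunConfig) -> Dict[str, StressField]:
    fields: Dict[str, StressField] = {}
    pressure_solver: Optional[StaticSolver] = None
    for c in cfg.cases:
        kind = c["kind"]
        if kind in ("hydrostatic", "pressure_series"):
            if pressure_solver is None:
                pressure_solver = StaticSolver(model, cfg.solver_strategy)
        if kind == "hydrostatic":
            p = float(c.get("pressure", DEFAULT_PRESSURE))
            fld = pressure_solver.solve(hydrostatic_case(model, p))
            fields[f"hydrostatic_{p:g}MPa"] = fld
        elif kind == "pressure_series":
            ps = [float(x) for x in c.get("pressures", PRESSURE_SERIES)]
            for p, fld in zip(ps, pressure_series(model, ps, pressure_solver)):
                fields[f"series_{p:g}MPa"] = fld
        else:
            loc = "chamber_wall" if kind == "point_chamber" else "suture"
            force = float(c.get("force", 10.0))
            if c.get("scale_to_area"):
                force = scale_point_force(
                    force, float(c["reference_area"]), _total_outer_area(model))
            case = point_load_case(model, loc, force,
                                   cap_half_angle_deg=float(c.get("cap_half_angle_deg", 10.0)))
            fields[case.name] = solve(model, case, "fixed")
    return fields


def _total_outer_area(model: TetModel) -> float:
    faces = model.faces_with_label(R.EXTERNAL_WALL)
    v = model.nodes
    return float(0.5 * np.linalg.norm(
        np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]]),
        axis=1).sum())


def run_experiment(config: RunConfig) -> Dict:
    """Execute a configured experiment; returns summaries and file paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    params = config.resolve_params()
    surface = generate_planispiral_shell(params)
    write_stl(surface, out / "shell.stl")
    model = extrude_to_tets(surface, region_thickness(params), n_layers=config.n_layers)
    quality = mesh_quality(model).summary()

    convergence = None
    if len(config.mesh_levels) >= 2:
        ladder = []
        for mult in config.mesh_levels:
            p_l = dataclasses.replace(
                params, rings_per_whorl=int(round(params.rings_per_whorl * mult)),
                ring_segments=2 * int(round(params.ring_segments * mult / 2)),
            )
            mdl = build_shell_model(p_l, config.n_layers)
            fld = StaticSolver(mdl, config.solver_strategy).solve(
                hydrostatic_case(mdl, DEFAULT_PRESSURE))
            sep = mdl.nodes_with_label(R.FINAL_SEPTUM_ADAPERTURAL, R.FINAL_SEPTUM_ADAPICAL)
            peak = float(fld.nodal_max_principal[sep].max())
            ladder.append((mult, peak))
        ok, level = convergence_check(ladder)
        convergence = {"ladder": ladder, "converged": ok, "chosen_level": level}

    fields = _case_fields(model, config)
    summaries = {name: summarize_case(fld, model) for name, fld in fields.items()}
    table = compare_table(summaries)
    table.to_csv(out / "case_summaries.csv")

    for name, fld in fields.items():
        write_vtk(model, out / f"{name}.vtk", field=fld)
        react = float(np.abs(fld.reaction_resultant()).sum())
        log.info("case %s: gross load %.4g N, net reactions %.3g N",
                 name, fld.gross_force, react)

    report = {
        "out_dir": str(out),
        "mesh_quality": quality,
        "convergence": convergence,
        "summaries": {k: v.as_dict() for k, v in summaries.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
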