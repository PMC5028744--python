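"""Comparative stress statistics: case summaries, percent decreases, transects.

The comparative quantities mirror the standard reporting for this kind of
study: a global average of the per-element maximum principal stress, regional
peaks of the nodal-averaged field (final septum; internal shell surface),
extrema through the septum thickness at the septum centre and at its ventral
margin, and the fraction of final-septum nodes exceeding the theoretical
tensile strength of nacre (about 130 MPa).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import regions as R
from .fea_solver import StressField, nodal_average
from .meshing import TetModel

NACRE_TENSILE_STRENGTH = 130.0  # MPa

#: boundary labels that make up the internal shell surface
INTERNAL_SHELL_LABELS = (R.WALL_INTERIOR, R.BODY_CHAMBER_INTERIOR)
#: labels of the final septum's two faces
FINAL_SEPTUM_LABELS = (R.FINAL_SEPTUM_ADAPERTURAL, R.FINAL_SEPTUM_ADAPICAL)


class PostprocessError(ValueError):
    pass


@dataclass
class CaseSummary:
    case_name: str
    global_avg_max_principal: float  # volume-weighted element average, MPa
    global_avg_unweighted: float  # arithmetic element average, MPa
    peak_final_septum: float  # MPa
    peak_internal_shell_surface: float  # MPa
    center_minmax: Tuple[float, float]  # (min, max) MPa
    ventral_margin_minmax: Tuple[float, float]  # (min, max) MPa
    exceedance_fraction: float  # final-septum nodes above the threshold
    threshold: float = NACRE_TENSILE_STRENGTH

    def as_dict(self) -> Dict[str, float]:
        return {
            "case": self.case_name,
            "avg_max_principal_MPa": self.global_avg_max_principal,
            "avg_max_principal_unweighted_MPa": self.global_avg_unweighted,
            "peak_final_septum_MPa": self.peak_final_septum,
            "peak_internal_shell_MPa": self.peak_internal_shell_surface,
            "center_min_MPa": self.center_minmax[0],
            "center_max_MPa": self.center_minmax[1],
            "ventral_min_MPa": self.ventral_margin_minmax[0],
            "ventral_max_MPa": self.ventral_margin_minmax[1],
            "exceedance_fraction": self.exceedance_fraction,
        }


def _local_probe(model: TetModel, nodal: np.ndarray, candidates: np.ndarray,
                 centre: np.ndarray, radius: float) -> Tuple[float, float]:
    d = np.linalg.norm(model.nodes[candidates] - centre, axis=1)
    sel = candidates[d <= radius]
    if len(sel) == 0:
        sel = candidates[np.argsort(d)[:4]]
    vals = nodal[sel]
    return float(vals.min()), float(vals.max())


def summarize_case(fld: StressField, model: TetModel,
                   threshold: float = NACRE_TENSILE_STRENGTH) -> CaseSummary:
    """Comparative statistics of a solved case.

    The septum "centre" is the node nearest the area centroid of the final
    septum (the centroid is foramen-adjusted by construction: the hole
    removes no labelled nodes but shifts no mass either way on a symmetric
    septum); the "ventral margin" is the final septum's suture node farthest
    from the coiling axis.  Both extrema are taken over the nodes of the two
    septal faces within a small probe radius, which realizes the reported
    through-thickness min/max "along a line connecting the adoral and
    adapical septum surfaces".
    """
    required = set(FINAL_SEPTUM_LABELS) & set(model.boundary_labels.tolist())
    if not required:
        raise PostprocessError("model lacks final-septum labels")

    vols = model.element_volumes()
    s1 = fld.sigma1
    global_avg = float((vols * s1).sum() / vols.sum())
    global_avg_unw = float(s1.mean())

    nodal = fld.nodal_max_principal
    sep_nodes = model.nodes_with_label(*FINAL_SEPTUM_LABELS)
    if len(sep_nodes) == 0:
        raise PostprocessError("no final-septum nodes")
    peak_sep = float(nodal[sep_nodes].max())

    int_nodes = model.nodes_with_label(*INTERNAL_SHELL_LABELS)
    peak_int = float(nodal[int_nodes].max()) if len(int_nodes) else math.nan

    sep_pos = model.nodes[sep_nodes]
    centroid = sep_pos.mean(axis=0)
    edge = float(np.median(np.linalg.norm(np.diff(sep_pos[:50], axis=0), axis=1)))
    probe = 2.0 * edge

    centre_node = sep_nodes[int(np.argmin(np.linalg.norm(sep_pos - centroid, axis=1)))]
    centre_mm = _local_probe(model, nodal, sep_nodes, model.nodes[centre_node], probe)

    suture = model.node_sets.get(R.SUTURE_BAND, np.empty(0, dtype=np.int64))
    margin_candidates = np.intersect1d(suture, sep_nodes)
    if len(margin_candidates) == 0:
        margin_candidates = sep_nodes
    rad = np.linalg.norm(model.nodes[margin_candidates][:, :2], axis=1)
    ventral_node = margin_candidates[int(np.argmax(rad))]
    ventral_mm = _local_probe(model, nodal, sep_nodes, model.nodes[ventral_node], probe)

    exceed = float((nodal[sep_nodes] > threshold).mean())

    return CaseSummary(
        case_name=fld.case_name,
        global_avg_max_principal=global_avg,
        global_avg_unweighted=global_avg_unw,
        peak_final_septum=peak_sep,
        peak_internal_shell_surface=peak_int,
        center_minmax=centre_mm,
        ventral_margin_minmax=ventral_mm,
        exceedance_fraction=exceed,
        threshold=threshold,
    )


def percent_decrease(reference: float, comparison: float) -> int:
    """Half-up integer percent decrease from ``reference`` to ``comparison``."""
    if reference <= 0:
        raise PostprocessError("reference must be > 0")
    return int(math.floor(100.0 * (reference - comparison) / reference + 0.5))


def transect(
    fld: StressField,
    model: TetModel,
    start: Sequence[float],
    end: Sequence[float],
    tube_radius: Optional[float] = None,
    node_subset: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Nodal sigma_1 profile along a straight transect.

    Nodes within ``tube_radius`` of the segment are sampled and ordered by
    arc position; the default radius is twice the local median node spacing.
    """
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    seg = p1 - p0
    L = float(np.linalg.norm(seg))
    if L == 0:
        raise PostprocessError("transect endpoints coincide")
    d_hat = seg / L
    ids = node_subset if node_subset is not None else np.arange(len(model.nodes))
    rel = model.nodes[ids] - p0
    s = rel @ d_hat
    perp = np.linalg.norm(rel - np.outer(s, d_hat), axis=1)
    if tube_radius is None:
        tube_radius = 0.05 * L
    sel = (perp <= tube_radius) & (s >= -tube_radius) & (s <= L + tube_radius)
    if not sel.any():
        raise PostprocessError("empty transect sample set")
    order = np.argsort(s[sel], kind="stable")
    return pd.DataFrame({
        "arc_position_mm": s[sel][order],
        "sigma1_MPa": fld.nodal_max_principal[ids[sel][order]],
        "node": ids[sel][order],
    })


def compare_table(cases: Mapping[str, CaseSummary]) -> pd.DataFrame:
    """Side-by-side case table (rows = statistics, columns = cases) with
    derived percent-decrease rows between chamber-wall and suture loads."""
    if not cases:
        raise PostprocessError("at least one case required")
    cols = {}
    for name, cs in cases.items():
        d = cs.as_dict()
        d.pop("case")
        cols[name] = d
    df = pd.DataFrame(cols)

    by_kind: Dict[str, Dict[str, str]] = {}
    for name in cases:
        for kind in ("chamber", "suture"):
            if kind in name:
                model_id = name.replace(kind, "").strip("_- ")
                by_kind.setdefault(model_id, {})[kind] = name
    peak_row: Dict[str, float] = {}
    avg_row: Dict[str, float] = {}
    for model_id, pair in by_kind.items():
        if {"chamber", "suture"} <= set(pair):
            ch, su = cases[pair["chamber"]], cases[pair["suture"]]
            if ch.peak_internal_shell_surface > 0:
                peak_row[pair["suture"]] = percent_decrease(
                    ch.peak_internal_shell_surface, su.peak_internal_shell_surface)
    if peak_row:
        df.loc["peak_decrease_suture_vs_chamber_pct"] = pd.Series(peak_row)
    return df
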