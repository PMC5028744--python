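"""Published reference values for the four CT-based specimen models.

The CT geometries behind the original comparative study (Nautilus pompilius,
Spirula spirula, and a Cadoceras sp. ammonitella meshed with 5 and with 10
septa) are not publicly deposited, so their absolute stress values cannot be
recomputed.  What can be recomputed exactly is the arithmetic that connects
the printed numbers: the surface-area scaling of the point forces, the
percent decreases between chamber-wall and suture loads, and the SSI-to-depth
conversion.  :func:`reproduce_reference_arithmetic` replays all of it and
flags the two known internal inconsistencies of the published tables instead
of silencing them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .load_cases import scale_point_force
from .postprocess import percent_decrease
from .ssi import DEPTH_PER_SSI, depth_from_ssi

# specimen general data: total surface area (mm^2), element/node counts,
# force exerted by the 8 MPa pressure (N), printed scaled point force (N)
SPECIMENS = pd.DataFrame(
    [
        ("cadoceras5", 6.70, 1_780_464, 428_535, 32.22, 10.00),
        ("cadoceras10", 8.36, 2_373_913, 517_318, 21.41, 12.48),
        ("spirula", 2720.99, 2_058_092, 583_565, 7262.31, 4063.45),
        ("nautilus", 152_400.35, 2_434_318, 723_832, 693_270.16, 227_590.56),
    ],
    columns=["model", "surface_area_mm2", "elements", "nodes",
             "pressure_force_8MPa_N", "printed_scaled_force_N"],
).set_index("model")

REFERENCE_FORCE_N = 10.0  # applied to the 5-septa Cadoceras model
REFERENCE_AREA_MM2 = 6.70

# selected maximum-principal-stress values (MPa) under the three load cases
STRESS_TABLE = pd.DataFrame(
    {
        "cadoceras10": dict(avg_8mpa=1.4, peak_septum_8mpa=332.18,
                            center=(21.92, 10.81), ventral=(119.10, 46.97),
                            avg_chamber=687.0, peak_chamber=18920.21,
                            avg_suture=735.44, peak_suture=7750.25),
        "cadoceras5": dict(avg_8mpa=-1.09, peak_septum_8mpa=293.14,
                           center=(22.10, -4.02), ventral=(183.75, 77.57),
                           avg_chamber=584.30, peak_chamber=17983.78,
                           avg_suture=552.22, peak_suture=10468.20),
        "spirula": dict(avg_8mpa=2.45, peak_septum_8mpa=154.0,
                        center=(88.54, 71.45), ventral=(110.27, 0.36),
                        avg_chamber=474.03, peak_chamber=47071.0,
                        avg_suture=416.89, peak_suture=28136.0),
        "nautilus": dict(avg_8mpa=4.25, peak_septum_8mpa=272.2,
                         center=(150.21, 97.10), ventral=(170.10, 32.62),
                         avg_chamber=254.58, peak_chamber=79987.09,
                         avg_suture=457.55, peak_suture=73318.09),
    }
).T

# printed percent-decrease claims (peak, chamber-wall -> suture)
PRINTED_PEAK_DECREASES = {"nautilus": 8, "spirula": 40, "cadoceras10": 59}
#: the 5-septa Cadoceras decrease is printed as 42% in the results text and
#: 41% in the discussion; 42 is the value consistent with the stress table
PRINTED_CADOCERAS5_DECREASE = (42, 41)

# Cadoceras global-average decreases, 10-septa relative to 5-septa printed
# the other way round: the printed 15%/25% match decrease from the 10-septa
# to the 5-septa averages
PRINTED_AVG_DECREASES = {"chamber": 15, "suture": 25}

# SSI table: radius of curvature (mm), SSI, printed depth (m)
SSI_TABLE = pd.DataFrame(
    [
        ("nautilus", "median", 18.39, 43.50, 1304.92),
        ("nautilus", "median", 23.87, 33.51, 1005.27),
        ("nautilus", "median", 25.05, 31.93, 957.97),
        ("nautilus", "median", 34.01, 23.52, 705.61),
        ("nautilus", "median", 25.76, 31.06, 931.66),
        ("nautilus", "median", 23.40, 34.18, 1025.53),
        ("nautilus", "median", 28.53, 28.04, 841.19),
        ("nautilus", "median", 22.52, 35.53, 1065.80),
        ("nautilus", "median", 21.87, 36.58, 1097.40),
        ("nautilus", "median", 28.65, 27.92, 837.73),
        ("nautilus", "transverse", 26.88, 29.76, 892.91),
        ("nautilus", "transverse", 59.11, 13.53, 406.00),
        ("spirula", "median", 3.14, 52.83, 1584.94),
        ("spirula", "median", 3.36, 49.34, 1480.13),
        ("spirula", "median", 3.78, 43.88, 1316.55),
        ("spirula", "median", 3.55, 46.72, 1401.49),
        ("spirula", "median", 3.26, 50.97, 1529.16),
    ],
    columns=["model", "section", "radius_mm", "ssi", "printed_depth_m"],
)


def reproduce_reference_arithmetic() -> pd.DataFrame:
    """Recompute every derived printed number from its printed inputs.

    Returns a claim-by-claim table with columns ``claim``, ``computed``,
    ``printed``, ``status`` (PASS / FLAG).  FLAG marks the two documented
    inconsistencies: the Spirula scaled point force (printed 4063.45 N vs the
    recomputed 4061.18 N) and the 41%-vs-42% Cadoceras 5-septa decrease.
    """
    rows: List[Dict] = []

    for model, row in SPECIMENS.iterrows():
        computed = scale_point_force(REFERENCE_FORCE_N, REFERENCE_AREA_MM2,
                                     row["surface_area_mm2"])
        printed = row["printed_scaled_force_N"]
        status = "PASS" if abs(computed - printed) <= 0.005 else "FLAG"
        rows.append(dict(claim=f"scaled_force_{model}", computed=computed,
                         printed=printed, status=status))

    for model, printed in PRINTED_PEAK_DECREASES.items():
        st = STRESS_TABLE.loc[model]
        computed = percent_decrease(st["peak_chamber"], st["peak_suture"])
        rows.append(dict(claim=f"peak_decrease_{model}", computed=computed,
                         printed=printed,
                         status="PASS" if computed == printed else "FLAG"))

    st5 = STRESS_TABLE.loc["cadoceras5"]
    computed5 = percent_decrease(st5["peak_chamber"], st5["peak_suture"])
    res, disc = PRINTED_CADOCERAS5_DECREASE
    rows.append(dict(claim="peak_decrease_cadoceras5", computed=computed5,
                     printed=res, status="PASS" if computed5 == res else "FLAG"))
    rows.append(dict(claim="peak_decrease_cadoceras5_alt", computed=computed5,
                     printed=disc,
                     status="FLAG"))  # documented 41 vs 42 conflict

    for kind, printed in PRINTED_AVG_DECREASES.items():
        ref = STRESS_TABLE.loc["cadoceras10", f"avg_{kind}"]
        cmp_ = STRESS_TABLE.loc["cadoceras5", f"avg_{kind}"]
        computed = percent_decrease(ref, cmp_)
        rows.append(dict(claim=f"avg_decrease_{kind}", computed=computed,
                         printed=printed,
                         status="PASS" if computed == printed else "FLAG"))

    for i, r in SSI_TABLE.iterrows():
        computed = depth_from_ssi(r["ssi"])
        rel = abs(computed - r["printed_depth_m"]) / r["printed_depth_m"]
        rows.append(dict(claim=f"ssi_depth_{r['model']}_{i}", computed=round(computed, 2),
                         printed=r["printed_depth_m"],
                         status="PASS" if rel <= 5e-4 else "FLAG"))

    return pd.DataFrame(rows)
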