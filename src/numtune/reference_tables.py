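"""Published per-participant summary tables of the 7-participant 7T study.

These small printed tables — behavioral task performance and the MNI-space
map-center coordinates of the temporal-occipital numerosity map (NTO) — are
the only participant-level quantities released with the study and serve as
inputs for cohort-level averaging.  Values are stored exactly as printed
(accuracies as integer percentages, d' to one decimal, coordinates in mm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["behavior_table", "nto_coordinates_table", "summarize_behavior", "average_nto_coordinates"]

_BEHAVIOR = [
    # participant, n_runs, catch accuracy %, embedded accuracy %, d'
    ("P1", 15, 79, 92, 3.4),
    ("P2", 16, 70, 88, 3.7),
    ("P3", 17, 95, 96, 4.2),
    ("P4", 16, 88, 92, 3.7),
    ("P5", 16, 78, 96, 3.5),
    ("P6", 16, 77, 93, 3.4),
    ("P7", 16, 95, 98, 4.3),
]

_NTO_MNI = [
    # participant, (left x, y, z), (right x, y, z)
    ("P1", (-47, -60, -9), (42, -71, -11)),
    ("P2", (-35, -80, -8), (35, -72, -8)),
    ("P3", (-39, -70, -6), (44, -71, -8)),
    ("P4", (-42, -70, -1), (40, -74, -5)),
    ("P5", (-36, -71, -12), (40, -81, -7)),
    ("P6", (-42, -61, -15), (41, -73, -14)),
    ("P7", (-39, -56, -7), (36, -77, -2)),
]


def behavior_table() -> pd.DataFrame:
    return pd.DataFrame(
        _BEHAVIOR, columns=["participant", "n_runs", "catch_acc", "embedded_acc", "dprime"]
    )


def nto_coordinates_table() -> pd.DataFrame:
    rows = []
    for p, left, right in _NTO_MNI:
        for hemi, (x, y, z) in (("left", left), ("right", right)):
            rows.append({"participant": p, "hemisphere": hemi, "x": x, "y": y, "z": z})
    return pd.DataFrame(rows)


def summarize_behavior() -> dict:
    """Cohort averages of the behavioral table, rounded as printed
    (accuracies to integer percent, d' to one decimal, SDs likewise)."""
    t = behavior_table()
    return {
        "n_runs_mean": int(round(t.n_runs.mean())),
        "catch_acc_mean": int(round(t.catch_acc.mean())),
        "catch_acc_sd": int(round(t.catch_acc.std(ddof=1))),
        "embedded_acc_mean": int(round(t.embedded_acc.mean())),
        "embedded_acc_sd": int(round(t.embedded_acc.std(ddof=1))),
        "dprime_mean": round(float(t.dprime.mean()), 1),
        "dprime_sd": round(float(t.dprime.std(ddof=1)), 1),
    }


def average_nto_coordinates() -> pd.DataFrame:
    """Across-participant mean (SD) of the NTO map-center MNI coordinates,
    rounded to integer mm as printed."""
    t = nto_coordinates_table()
    out = []
    for hemi, sub in t.groupby("hemisphere"):
        row = {"hemisphere": hemi, "n": len(sub)}
        for c in "xyz":
            row[f"{c}_mean"] = int(np.round(sub[c].mean()))
            row[f"{c}_sd"] = int(np.round(sub[c].std(ddof=1)))
        out.append(row)
    return pd.DataFrame(out).sort_values("hemisphere", ascending=False).reset_index(drop=True)
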