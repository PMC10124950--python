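"""Score the simulated behavior and recompute the published cohort averages.

Scores each simulated participant's button presses against the labeled task
trials (2 s hit window), reports per-class accuracy and d', and recomputes
the cohort rows of the published per-participant tables: behavioral task
performance (embedded-trial accuracy, catch-trial d') and the map-center MNI
coordinates of the temporal-occipital numerosity map.

Reads results/cohort/; writes results/behavior_simulated.tsv,
results/behavior_published_summary.tsv and results/nto_coordinates_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from numtune.design import build_symbolic_run, inject_task_trials, symbolic_config
from numtune.io import read_events, sequence_from_events
from numtune.reference_tables import average_nto_coordinates, summarize_behavior
from numtune.stats import dprime

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"


def main() -> None:
    rows = []
    if COHORT.exists():
        seq = sequence_from_events(read_events(COHORT / "events_symbolic.tsv"), symbolic_config())
        for path in sorted(COHORT.glob("sub-*_responses.tsv")):
            sub = int(path.name.split("_")[0].split("-")[1])
            rts = pd.read_csv(path, sep="\t")["response_time"].to_numpy()
            beh = dprime(seq, rts)
            rows.append(
                {
                    "participant": sub,
                    "pct_embedded": round(beh.pct_correct["embedded_target"], 1),
                    "pct_catch": round(beh.pct_correct["catch_target"], 1),
                    "false_alarms": beh.false_alarms,
                    "dprime": round(beh.dprime, 2),
                }
            )
        sim = pd.DataFrame(rows)
        sim.to_csv(RESULTS / "behavior_simulated.tsv", sep="\t", index=False)
        print("simulated cohort:")
        print(
            f"  embedded {sim.pct_embedded.mean():.1f}%, catch {sim.pct_catch.mean():.1f}%, "
            f"d' {sim.dprime.mean():.2f} +/- {sim.dprime.std(ddof=1):.2f}"
        )
    else:
        print("no simulated cohort found (run 02_simulate_cohort.py); reporting published tables only")

    pub = summarize_behavior()
    pd.DataFrame([pub]).to_csv(RESULTS / "behavior_published_summary.tsv", sep="\t", index=False)
    print(
        "published cohort averages: embedded "
        f"{pub['embedded_acc_mean']} +/- {pub['embedded_acc_sd']}%, catch d' "
        f"{pub['dprime_mean']} +/- {pub['dprime_sd']}"
    )
    coords = average_nto_coordinates()
    coords.to_csv(RESULTS / "nto_coordinates_summary.tsv", sep="\t", index=False)
    left = coords.set_index("hemisphere").loc["left"]
    print(
        f"map center, left hemisphere (MNI): x = {left.x_mean} ({left.x_sd}), "
        f"y = {left.y_mean} ({left.y_sd}), z = {left.z_mean} ({left.z_sd})"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
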