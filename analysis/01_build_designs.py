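"""Build the two run designs and check their timing arithmetic.

Constructs the numerosity-localizer run (dots 1-7, baseline 20, white-dot
task at 10%) and the symbolic-number run (digits 1-7, baseline 0, embedded/
catch/distractor task at 20%), writes both event tables, and prints the
block arithmetic: with the default 650 ms SOA and 1.95 s TR each value block
lasts 3.9 s (2 TRs), each baseline block 15.6 s (8 TRs), and a run is 182
TRs = 354.9 s.
"""

import sys
from pathlib import Path

import pandas as pd

from numtune.design import build_numerosity_run, build_symbolic_run, inject_task_trials
from numtune.io import write_events

SEED = 20230419
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, build in (("localizer", build_numerosity_run), ("symbolic", build_symbolic_run)):
        seq = inject_task_trials(build(), seed=SEED)
        write_events(OUT / f"events_{name}.tsv", seq)
        cfg = seq.config
        rows.append(
            {
                "experiment": name,
                "n_presentations": seq.n_presentations,
                "value_block_s": cfg.reps_per_value * cfg.soa,
                "baseline_block_s": cfg.baseline_reps * cfg.soa,
                "n_trs_total": seq.n_trs_total,
                "run_duration_s": seq.duration,
                "n_task_trials": seq.metadata["n_task_trials"],
                "task_rate": round(seq.metadata["achieved_task_rate"], 4),
            }
        )
        print(
            f"{name}: {seq.n_presentations} presentations, value blocks "
            f"{cfg.reps_per_value * cfg.soa:.1f} s, baseline {cfg.baseline_reps * cfg.soa:.1f} s, "
            f"{seq.n_trs_total} TRs ({seq.duration:.1f} s), "
            f"{seq.metadata['n_task_trials']} task trials "
            f"({100 * seq.metadata['achieved_task_rate']:.1f}%)"
        )
    pd.DataFrame(rows).to_csv(OUT / "design_summary.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'design_summary.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
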