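"""Split-half cross-validated model comparison and the cohort-level tests.

Per participant and ROI: split the 16 runs into odd/even halves, compute the
cross-validated variance explained of the tuning model and the GLM, their
difference (delta VE), and the proportion of voxels better explained by
tuning.  Across the 7 participants: an exact one-sided Wilcoxon signed-rank
test of whether each ROI's mean delta VE exceeds zero, and a paired t test
comparing the two ROIs.

Reads results/cohort/; writes results/crossval_voxels.tsv,
results/crossval_roi_summary.tsv, results/crossval_tests.tsv and a
VE-vs-VE diagnostic scatter (results/crossval_scatter.png).
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from numtune.crossval import proportion_tuned, split_half_cv
from numtune.design import symbolic_config
from numtune.fitting import PredictionGrid, default_fit_config
from numtune.io import read_bold, read_events, sequence_from_events
from numtune.models import HRFParams
from numtune.stats import t_tests, wilcoxon_exact

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"


def main() -> None:
    if not COHORT.exists():
        print("run 02_simulate_cohort.py first", file=sys.stderr)
        return 1
    seq = sequence_from_events(read_events(COHORT / "events_symbolic.tsv"), symbolic_config())
    hrf = HRFParams()
    cfg = default_fit_config("linear", refine=False)
    grid = PredictionGrid(seq, hrf, cfg, "linear")

    vox_rows, roi_rows = [], []
    for path in sorted(COHORT.glob("sub-*_roi-*_bold.nii.gz")):
        sub = int(path.name.split("_")[0].split("-")[1])
        roi = path.name.split("_")[1].split("-")[1]
        runs = read_bold(path, expected_tr=seq.config.tr)
        cv = split_half_cv(runs, seq, hrf, cfg, "linear", grid)
        for v in range(len(cv.delta_ve)):
            vox_rows.append(
                {
                    "participant": sub,
                    "roi": roi,
                    "voxel": v,
                    "ve_prf": cv.ve_prf[v],
                    "ve_glm": cv.ve_glm[v],
                    "delta_ve": cv.delta_ve[v],
                    "valid": bool(cv.valid[v]),
                }
            )
        roi_rows.append(
            {
                "participant": sub,
                "roi": roi,
                "mean_delta_ve": float(cv.delta_ve.mean()),
                "proportion_tuned": proportion_tuned(cv, require_valid=False),
                "n_valid": int(cv.valid.sum()),
            }
        )
    vox = pd.DataFrame(vox_rows)
    roi = pd.DataFrame(roi_rows)
    vox.to_csv(RESULTS / "crossval_voxels.tsv", sep="\t", index=False)
    roi.to_csv(RESULTS / "crossval_roi_summary.tsv", sep="\t", index=False)

    wide = roi.pivot(index="participant", columns="roi", values="mean_delta_ve")
    tests = []
    for side in ("left", "right"):
        w = wilcoxon_exact(wide[side].to_numpy(), tail="one_sided")
        tests.append({"test": f"wilcoxon_delta_ve_gt0_{side}", "statistic": w.statistic, "p": w.p})
        print(f"{side} ROI: mean delta VE = {wide[side].mean():+.3f}, exact Wilcoxon one-sided p = {w.p:.4f}")
    t = t_tests(wide["left"].to_numpy(), wide["right"].to_numpy(), kind="paired")
    tests.append({"test": "paired_t_left_vs_right", "statistic": t.statistic, "p": t.p})
    print(f"left vs right delta VE: paired t({t.df}) = {t.statistic:.2f}, p = {t.p:.4f}")
    for side in ("left", "right"):
        props = roi[roi.roi == side].proportion_tuned
        print(f"{side} ROI: proportion of voxels better explained by tuning = {props.mean():.2f} +/- {props.std(ddof=1):.2f}")
    pd.DataFrame(tests).to_csv(RESULTS / "crossval_tests.tsv", sep="\t", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharex=True, sharey=True)
    for ax, side in zip(axes, ("left", "right")):
        sub = vox[vox.roi == side]
        ax.scatter(sub.ve_glm, sub.ve_prf, s=8, alpha=0.5)
        lim = (-0.1, 1.05)
        ax.plot(lim, lim, "k-", lw=0.8)
        ax.set(title=f"{side} ROI", xlabel="cross-validated VE (GLM)", xlim=lim, ylim=lim)
    axes[0].set_ylabel("cross-validated VE (pRF)")
    fig.tight_layout()
    fig.savefig(RESULTS / "crossval_scatter.png", dpi=120)
    print(f"wrote {RESULTS / 'crossval_scatter.png'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
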