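# Methods

`numtune` implements a model-based analysis of fMRI responses to numerical
magnitude: forward tuning models predict voxel time series from a stimulus
sequence, the models are fitted per voxel, and a cross-validated comparison
asks whether a voxel's activity is better described by magnitude *tuning*
than by an untuned stimulus-driven response. A synthetic-data generator with
known ground truth stands in for raw scanner data, so every stage is
testable end to end.

## Stimulus designs

Both experiments share one temporal skeleton. Stimuli appear for 300 ms at a
650 ms stimulus-onset asynchrony; six repeats of the same magnitude form a
3.9 s block, exactly 2 TRs at TR = 1.95 s. One cycle is an ascending sweep
through the main values 1–7, a 15.6 s baseline block (8 TRs), the descending
sweep, and a second baseline block; four cycles plus six discarded dummy TRs
give a 182-TR (354.9 s) run with 176 analyzed TRs and 528 presentations.

The numerosity localizer shows dot patterns with baseline numerosity 20 and
a white-dot attention task on 10% of presentations. The symbolic run shows
Arabic digits with baseline digit 0 and a number-detection task: the +1
increments inside the ascending limb (including the 0→1 step out of
baseline, seven per cycle) are *embedded* targets; *catch* targets (a digit
one larger than its predecessor) and letter *distractors* (morphologically
similar to the digit a catch would have shown: L, Z, E, A, S, G, T, B)
replace randomly chosen main presentations so that together they are 20% of
all presentations, rounded to the nearest achievable count and recorded in
the sequence metadata. Special trials are never placed adjacent to one
another; whether they replace or extend the sequence was an open choice — we
replace, keeping run length fixed. The baseline magnitude (20 or 0) is a
real stimulus that passes through the tuning function, not a rest condition.

Time origin is the first analyzed TR. A TR's stimulus value is the value
presented during it (the block design makes this unique, using half-open TR
intervals).

## Forward model

A recording site's aggregate tuning is a one-dimensional Gaussian over
magnitude: logarithmic for numerosity, `exp(−(ln s − ln μ)²/2σ²)`, with σ in
natural-log units; linear for symbolic numbers, `exp(−(s − μ)²/2σ²)`. The
log model is only ever used with the localizer (all magnitudes > 0); the
linear model accepts s = 0. The neural prediction for a run is a train of
300 ms boxcars scaled by the tuning response to each presented magnitude
(letter distractors carry no magnitude and contribute zero). Convolution
with a hemodynamic response function and averaging within TR intervals
yields the per-TR prediction, which an amplitude β and offset scale and
shift.

The HRF is a difference of two gamma densities, each parameterized so its
mode sits at the stated delay (shape = 1 + delay/dispersion). Defaults:
peak delay 6 s, undershoot delay 16 s, dispersions 1 s, undershoot ratio
1/6, kernel length 32 s, peak-normalized to 1 so the response scale lives in
β. No specific published parameterization is being matched; participant-
level refitting (below) absorbs deviations. The fine simulation grid is
dt = 0.05 s, which divides the 300 ms duration, 650 ms SOA and 1.95 s TR
exactly.

Because convolution followed by TR-averaging is linear in the per-
presentation amplitudes, the package precomputes a per-event response basis
(n_events × n_TRs); any prediction is then a single matrix product, which is
what makes exhaustive grid fitting cheap. Batched and direct predictions
agree to machine precision (tested).

## Estimation

**pRF fit.** Exhaustive search over a (μ, σ) candidate grid; for each
candidate the optimal β and offset have a closed form, so scanning all
candidates against a voxel is one matrix-vector product. Grids: μ log-spaced
over [0.5, 14] (80 steps, localizer/log) or linear over [−1, 14] (symbolic),
σ log-spaced over [0.05, 5] log-units or [0.1, 10] stimulus units (40
steps) — deliberately wider than the presented range 1–7 so out-of-range
preferences are attainable rather than clipped. Exact RSS ties break to the
smallest μ, then smallest σ (candidates are scanned in that order).
Candidates whose prediction is effectively constant (centered sum of squares
below 1e−30) are treated as degenerate with β = 0. The grid optimum is
polished by bounded Nelder–Mead (tolerance 1e−4 in parameter units) and the
refined result is kept only if it does not increase RSS. Goodness of fit is
variance explained, R² = 1 − RSS/TSS with the offset fitted — not a squared
correlation — so cross-validated values may be negative. A constant input
series is flagged degenerate with R² = 0.

**GLM.** Ordinary least squares on [HRF-convolved main-vs-baseline
regressor, intercept]; the contrast t is the coefficient over its standard
error at residual df. A numerically perfect fit would give an infinite t; it
is reported as 1e12.

**HRF refit.** Holding each well-fit voxel's (μ, σ) fixed (R² ≥ threshold
under the canonical HRF), peak delay and undershoot ratio are optimized to
maximize summed R², with β/offset re-solved in closed form. Only two HRF
parameters are freed to avoid degeneracy with tuning width. The estimate is
returned only if it does not lower the objective relative to the initial
parameters.

**Exclusions.** Voxels are kept iff R² ≥ 0.30 and μ lies inside the
presented range [1, 7], inclusive.

## Split-half cross-validation

Runs are split by odd/even index (1-based). Per half: runs are averaged and
both models fitted. The training-half prediction — tuning parameters frozen,
scale and offset refit — is evaluated against the other half's averaged
series by R²; the two directions are averaged per voxel. ΔVE = VE_pRF −
VE_GLM; a site with ΔVE > 0 is better explained by tuning (exact ties count
as not-better). Negative ΔVE is retained. By default the proportion of
tuned sites is computed over voxels passing the exclusion rule in *both*
halves (dropped voxels are counted in the result's metadata); a
`require_valid=False` escape hatch exists for null analyses where the
exclusion rule itself is under study.

## Behavior and statistics

**d′.** Responses are matched greedily to the most recent unanswered target
(embedded or catch) within a 2 s window; matched responses are hits,
everything else a false alarm. Percentage correct is reported per target
class. d′ = z(hit rate) − z(false-alarm rate) from the pooled target hit
rate; the log-linear correction ((count + 0.5)/(n + 1)) is applied only to
rates of exactly 0 or 1, so unsaturated rates reproduce the textbook closed
form. The false-alarm denominator is not fixed by the scoring rule alone;
we use the number of distractor presentations when any exist, else all
non-target presentations.

**Exact Wilcoxon signed-rank.** At cohort sizes like n = 7 only the exact
null distribution reproduces printed p-values (e.g. a one-sided p of
5/128 = 0.0391 when the negative ranks sum to 3), so the test enumerates all
2ⁿ sign assignments (n ≤ 25), drops zeros, and average-ranks ties. The
two-sided p doubles the smaller tail, capped at 1. Cross-checked against
scipy's exact method and an independent brute-force enumeration in the
tests.

**RM-ANOVA.** Two within-participant factors (map × hemisphere); each
effect is tested against its interaction with participant, the standard
univariate repeated-measures layout, with Bonferroni-corrected pairwise
paired t comparisons between levels of the first factor. The published
df (5, 78) for a 7-participant 6 × 2 design does not correspond to this
textbook layout (which gives (5, 30)); we implement the standard layout.

**Effective-n correlation.** When voxels have been upsampled onto a finer
surface, neighboring points are not independent: r is computed on all
points, but its p-value uses n_eff = ceil(n/factor) via the t transform.
The factor is a required user parameter.

## Synthetic data

The generator emulates what the analysis assumes: a 1-D cortical sheet with
preferred magnitude laid out monotonically (log-spaced for log models),
Gaussian-tuned voxels with common width σ (default 0.5 log-units / 1.0
stimulus units — a mid-range tuning width at which neighboring magnitudes
overlap but remain discriminable), optional untuned voxels that respond
with unit amplitude to every non-baseline presentation (the GLM's generative
counterpart), additive Gaussian noise per TR (i.i.d. by default; optional
AR(1) with ρ = 0.3 to mimic BOLD autocorrelation, innovation-scaled so the
marginal SD stays as requested), and 16 runs per participant by default.
The behavioral responder answers each target with a class-specific hit
probability at a truncated-normal latency (defaults: embedded 0.94, catch
0.84 — the published cohort hit rates — false alarms on 5% of distractors,
RT 0.6 ± 0.15 s).

What the generator does *not* emulate: 2-D cortical geometry and map
borders, spatial noise correlations between voxels, scanner drift and
physiological confounds, HRF variability across voxels, and trial-to-trial
neural variability (noise is additive on the BOLD series). Passing tests
therefore certify the estimation and comparison machinery under the model's
own assumptions, not robustness to real-data artifacts.

Analysis problem sizes (7 participants × 2 ROIs × 40 voxels × 16 runs;
200-voxel recovery cohorts) were chosen so the full suite and the analysis
scripts run comfortably on a laptop-class single core while keeping binomial
and CLT-based checks well-powered.

## Known limitations

- Preferences far outside the presented range are weakly identified: only
  the Gaussian's tail is constrained, so (μ, σ, β) trade off. Such fits are
  excluded by the range rule, which is the rule's purpose.
- The exact Wilcoxon enumeration is O(2ⁿ) and capped at n = 25.
- The HRF refit frees two parameters only; genuinely different undershoot
  timing is absorbed by β and the tuning parameters.
- `from_files` mode expects the package's own NIfTI layout (voxels on the
  first axis, runs concatenated in time, run structure in the header
  description) or plain TSV; it is not a general neuroimaging reader.
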