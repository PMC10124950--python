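"""Behavioral d-prime and the statistical tests used by the analysis.

The Wilcoxon signed-rank test is implemented by exact enumeration of all 2^n
sign assignments because at the cohort sizes involved (n = 7 participants)
the printed p-values are only reproducible from the exact null distribution,
not from the large-sample normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StimulusSequence

__all__ = [
    "BehaviorSummary",
    "TestResult",
    "dprime",
    "dprime_from_rates",
    "wilcoxon_exact",
    "t_tests",
    "rm_anova_two_way",
    "pearson_effective_n",
    "recovery_metrics",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    tail: str
    df: float | tuple | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class BehaviorSummary:
    hits: dict
    misses: dict
    n_targets: dict
    false_alarms: int
    n_noise: int
    hit_rate: float
    fa_rate: float
    dprime: float
    pct_correct: dict


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hit rate) - z(false-alarm rate)."""
    return float(sps.norm.ppf(hit_rate) - sps.norm.ppf(fa_rate))


def _loglinear(count: int, n: int) -> float:
    """Log-linear corrected rate, used only when the raw rate is 0 or 1."""
    return (count + 0.5) / (n + 1)


def dprime(events: StimulusSequence | list, responses, window: float = 2.0) -> BehaviorSummary:
    """Score button presses against labeled task trials and compute d'.

    A response is a hit if it falls within ``window`` seconds after the most
    recent unanswered target (embedded or catch); any other response is a
    false alarm.  Percentage correct is reported per target class; d' is
    computed from the pooled target hit rate and the false-alarm rate, with
    the log-linear correction applied to rates of exactly 0 or 1.  The
    false-alarm rate denominator is the number of distractor presentations
    (all non-target presentations if there are no distractors).
    """
    ev = events.events if isinstance(events, StimulusSequence) else list(events)
    targets = [e for e in ev if e.trial_type in ("embedded_target", "catch_target")]
    if not targets:
        raise ValueError("no target trials in the event list")
    distractors = [e for e in ev if e.trial_type == "distractor"]
    responses = np.sort(np.asarray(responses, dtype=float))

    hits = {"embedded_target": 0, "catch_target": 0}
    answered = np.zeros(len(targets), dtype=bool)
    onsets = np.array([t.onset for t in targets])
    n_fa = 0
    for r in responses:
        lag = r - onsets
        eligible = np.where((lag >= 0) & (lag <= window) & ~answered)[0]
        if eligible.size:
            i = int(eligible[np.argmin(lag[eligible])])  # most recent target
            answered[i] = True
            hits[targets[i].trial_type] += 1
        else:
            n_fa += 1

    n_targets = {
        k: sum(t.trial_type == k for t in targets) for k in ("embedded_target", "catch_target")
    }
    pct = {
        k: 100.0 * hits[k] / n_targets[k] if n_targets[k] else np.nan for k in n_targets
    }
    total_hits = sum(hits.values())
    total_targets = len(targets)
    n_noise = len(distractors) if distractors else sum(
        e.trial_type not in ("embedded_target", "catch_target") for e in ev
    )
    hr = total_hits / total_targets
    far = n_fa / n_noise if n_noise else 0.0
    hr_c = _loglinear(total_hits, total_targets) if hr in (0.0, 1.0) else hr
    far_c = _loglinear(n_fa, n_noise) if far in (0.0, 1.0) else far
    return BehaviorSummary(
        hits=hits,
        misses={k: n_targets[k] - hits[k] for k in n_targets},
        n_targets=n_targets,
        false_alarms=n_fa,
        n_noise=n_noise,
        hit_rate=hr,
        fa_rate=far,
        dprime=dprime_from_rates(hr_c, far_c),
        pct_correct=pct,
    )


def wilcoxon_exact(diffs, tail: str = "one_sided") -> TestResult:
    """Exact Wilcoxon signed-rank test by full enumeration of sign assignments.

    Zeros are dropped; ties receive average ranks.  The one-sided tail tests
    for a positive median shift, P(W+ >= observed) under the exchangeable
    null; the two-sided p doubles the smaller tail (capped at 1).  Restricted
    to n <= 25 where the 2^n enumeration is tractable.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25; use a normal approximation")
    if tail not in ("one_sided", "two_sided"):
        raise ValueError("tail must be 'one_sided' or 'two_sided'")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # all 2^n values of W+ via iterative doubling
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    p_ge = float(np.mean(sums >= w_plus - eps))
    p_le = float(np.mean(sums <= w_plus + eps))
    p = p_ge if tail == "one_sided" else min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(statistic=w_plus, p=p, tail=tail, df=None, extra={"n": n})


def t_tests(x, y=None, kind: str = "one_sample") -> TestResult:
    """One-sample (against 0) or paired t test, two-sided."""
    x = np.asarray(x, dtype=float)
    if kind == "one_sample":
        d = x
    elif kind == "paired":
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
    else:
        raise ValueError("kind must be 'one_sample' or 'paired'")
    if d.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(d == d[0]) and d[0] != 0:
        raise ValueError("zero variance with nonzero mean: t undefined")
    res = sps.ttest_1samp(d, 0.0)
    stat = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return TestResult(statistic=stat, p=p, tail="two_sided", df=d.size - 1)


def _cell_table(table) -> np.ndarray:
    """Coerce input to a subjects x A-levels x B-levels array."""
    if isinstance(table, pd.DataFrame):
        req = {"participant", "factor_a", "factor_b", "value"}
        if not req.issubset(table.columns):
            raise ValueError(f"long-format table needs columns {sorted(req)}")
        pivot = table.pivot_table(
            index="participant", columns=["factor_a", "factor_b"], values="value", aggfunc="mean"
        )
        if pivot.isna().any().any():
            raise ValueError("unbalanced table: every participant needs every factor cell")
        a_levels = pivot.columns.get_level_values(0).unique()
        b_levels = pivot.columns.get_level_values(1).unique()
        arr = np.empty((pivot.shape[0], a_levels.size, b_levels.size))
        for i, a in enumerate(a_levels):
            for j, b in enumerate(b_levels):
                arr[:, i, j] = pivot[(a, b)].to_numpy()
        return arr
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected participants x factorA x factorB")
    if np.any(~np.isfinite(arr)):
        raise ValueError("unbalanced table: missing cells are not supported")
    return arr


def rm_anova_two_way(table) -> dict:
    """Two-way repeated-measures ANOVA (both factors within participant).

    Each effect is tested against its interaction with participant (the
    standard univariate RM layout).  Returns TestResults for factor A, factor
    B and A x B, plus Bonferroni-corrected pairwise paired-t comparisons
    between levels of factor A (averaged over factor B).
    """
    y = _cell_table(table)
    ns, a, b = y.shape
    if ns < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 participants and >= 2 levels per factor")
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = ns * b * np.sum((m_a - g) ** 2)
    ss_b = ns * a * np.sum((m_b - g) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = b * np.sum((m_as - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = a * np.sum((m_bs - m_s[:, None] - m_b[None, :] + g) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - g
    )
    ss_abs = np.sum(resid**2)

    def effect(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = np.inf if ms_eff > 0 else 0.0
            p = 0.0 if ms_eff > 0 else 1.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err))
        return TestResult(
            statistic=float(f), p=p, tail="two_sided", df=(df_eff, df_err),
            extra={"ss": float(ss_eff), "ss_error": float(ss_err)},
        )

    res = {
        "factor_a": effect(ss_a, a - 1, ss_as, (a - 1) * (ns - 1)),
        "factor_b": effect(ss_b, b - 1, ss_bs, (b - 1) * (ns - 1)),
        "interaction": effect(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (ns - 1)),
    }

    pairs = []
    n_pairs = a * (a - 1) // 2
    for i, j in itertools.combinations(range(a), 2):
        di = m_as[:, i] - m_as[:, j]
        if np.all(di == 0):
            pairs.append({"levels": (i, j), "t": 0.0, "p_bonf": 1.0})
            continue
        t = sps.ttest_1samp(di, 0.0)
        pairs.append(
            {
                "levels": (i, j),
                "t": float(t.statistic),
                "p_bonf": float(min(1.0, t.pvalue * n_pairs)),
            }
        )
    res["pairwise_a"] = pairs
    return res


def pearson_effective_n(x, y, upsample_factor: float = 1.0) -> TestResult:
    """Pearson correlation with the p-value computed at a reduced effective n.

    When data have been upsampled (e.g., voxels interpolated onto a finer
    surface), neighboring points are not independent; the correlation r is
    computed on all points but its probability uses n_eff = ceil(n / factor)
    degrees of freedom via the t transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    n_eff = math.ceil(x.size / upsample_factor)
    if n_eff < 3:
        raise ValueError(f"effective n = {n_eff} too small for a correlation test")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n_eff - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n_eff - 2))
    return TestResult(statistic=r, p=p, tail="two_sided", df=n_eff - 2, extra={"n_eff": n_eff})


def recovery_metrics(truth, fits) -> pd.DataFrame:
    """Bias and RMSE of fitted vs ground-truth tuning parameters.

    Untuned ground-truth voxels (no tuning model) are skipped.  Rows: mu,
    ln_mu, sigma, beta.
    """
    if len(truth) != len(fits):
        raise ValueError("truth and fits must have equal length")
    rows = []
    pairs = [(t, f) for t, f in zip(truth, fits) if t.tuning is not None]
    if not pairs:
        return pd.DataFrame(columns=["parameter", "bias", "rmse", "n"])
    for name, true_vals, fit_vals in (
        ("mu", [t.tuning.mu for t, _ in pairs], [f.model.mu for _, f in pairs]),
        (
            "ln_mu",
            [np.log(t.tuning.mu) if t.tuning.mu > 0 else np.nan for t, _ in pairs],
            [np.log(f.model.mu) if f.model.mu > 0 else np.nan for _, f in pairs],
        ),
        ("sigma", [t.tuning.sigma for t, _ in pairs], [f.model.sigma for _, f in pairs]),
        ("beta", [t.amplitude for t, _ in pairs], [f.beta for _, f in pairs]),
    ):
        err = np.asarray(fit_vals, dtype=float) - np.asarray(true_vals, dtype=float)
        err = err[np.isfinite(err)]
        rows.append(
            {
                "parameter": name,
                "bias": float(err.mean()) if err.size else np.nan,
                "rmse": float(np.sqrt(np.mean(err**2))) if err.size else np.nan,
                "n": int(err.size),
            }
        )
    return pd.DataFrame(rows)
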