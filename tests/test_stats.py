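"""Behavioral d', exact Wilcoxon, t tests, RM-ANOVA, effective-n correlation."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from numtune.design import PresentationEvent
from numtune.stats import (
    dprime,
    dprime_from_rates,
    pearson_effective_n,
    recovery_metrics,
    rm_anova_two_way,
    t_tests,
    wilcoxon_exact,
)


def _target(onset, kind="embedded_target"):
    return PresentationEvent(onset=onset, duration=0.3, value=2, trial_type=kind, symbol="2")


def _main(onset):
    return PresentationEvent(onset=onset, duration=0.3, value=1, trial_type="main", symbol="1")


def _distractor(onset):
    return PresentationEvent(onset=onset, duration=0.3, value=1, trial_type="distractor", symbol="Z")


class TestDprime:
    def test_closed_form_rates(self):
        assert dprime_from_rates(0.9, 0.1) == pytest.approx(2 * sps.norm.ppf(0.9), abs=1e-9)
        assert dprime_from_rates(0.6, 0.6) == 0.0

    def test_two_second_window_boundary(self):
        events = [_target(0.0), _main(10.0), _distractor(20.0), _target(30.0)]
        beh = dprime(events, [1.9, 32.1])  # 1.9 s after 1st target; 2.1 s after 2nd
        assert sum(beh.hits.values()) == 1
        assert beh.false_alarms == 1

    def test_per_class_percent_correct(self):
        events = [_target(0.0), _target(10.0, "catch_target"), _target(20.0, "catch_target"), _distractor(30.0)]
        beh = dprime(events, [0.5, 10.5])
        assert beh.pct_correct["embedded_target"] == 100.0
        assert beh.pct_correct["catch_target"] == 50.0

    def test_ceiling_rates_corrected_to_finite_dprime(self):
        events = [_target(i * 10.0) for i in range(5)] + [_distractor(100.0)]
        beh = dprime(events, [i * 10.0 + 0.5 for i in range(5)])
        assert np.isfinite(beh.dprime) and beh.dprime > 0

    def test_increasing_in_hit_rate(self):
        ds = [dprime_from_rates(h, 0.1) for h in (0.5, 0.7, 0.9)]
        assert ds == sorted(ds)

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="target"):
            dprime([_main(0.0)], [])


class TestWilcoxonExact:
    def test_all_positive_extreme_case(self):
        r = wilcoxon_exact([1, 2, 3, 4, 5, 6, 7], tail="one_sided")
        assert r.statistic == 28
        assert r.p == pytest.approx(1 / 128)

    def test_negative_rank_sum_three_matches_printed_p(self):
        r = wilcoxon_exact([1, 2, -3, 4, 5, 6, 7], tail="one_sided")
        assert r.statistic == 25
        assert r.p == pytest.approx(5 / 128)
        assert round(r.p, 4) == 0.0391

    def test_matches_scipy_exact_two_sided(self, rng):
        d = rng.normal(0.4, 1.0, size=12)
        ours = wilcoxon_exact(d, tail="two_sided")
        ref = sps.wilcoxon(d, method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_full_enumeration_oracle(self):
        # independent oracle: explicit loop over all sign assignments
        d = np.array([0.3, -1.2, 2.1, 0.7, -0.2, 1.5])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            sum(r for r, s in zip(ranks, signs) if s) >= w_obs - 1e-9
            for signs in itertools.product([0, 1], repeat=6)
        )
        r = wilcoxon_exact(d, tail="one_sided")
        assert r.p == pytest.approx(count / 64)

    def test_normal_approximation_agrees_at_n20(self, rng):
        d = rng.normal(0.3, 1.0, size=20)
        exact = wilcoxon_exact(d, tail="one_sided").p
        ranks = sps.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        n = 20
        mean, sd = n * (n + 1) / 4, np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        approx = sps.norm.sf((w - 0.5 - mean) / sd)  # continuity-corrected
        assert abs(exact - approx) < 0.005

    def test_distribution_sums_to_one_and_symmetric(self):
        n = 6
        ranks = np.arange(1, n + 1)
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = n * (n + 1) / 2
        pmf = {w: np.mean(sums == w) for w in np.unique(sums)}
        assert sum(pmf.values()) == pytest.approx(1.0)
        for w, p in pmf.items():
            assert p == pytest.approx(pmf[total - w])

    def test_zeros_dropped_and_all_zero_rejected(self):
        r = wilcoxon_exact([0.0, 1.0, 2.0, 0.0, 3.0], tail="one_sided")
        assert r.extra["n"] == 3
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_exact([0.0, 0.0])


class TestTTests:
    def test_printed_t_and_p(self):
        # a t of 4.53 at 6 degrees of freedom has a two-sided p near 0.004
        p = 2 * sps.t.sf(4.53, 6)
        assert round(p, 3) == 0.004

    def test_paired_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        r = t_tests(x, x, kind="paired")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_matches_direct_formula(self, rng):
        x = rng.normal(0.5, 1.0, size=9)
        r = t_tests(x, kind="one_sample")
        t_direct = x.mean() / (x.std(ddof=1) / 3)
        assert r.statistic == pytest.approx(t_direct, abs=1e-12)
        assert r.p == pytest.approx(2 * sps.t.sf(abs(t_direct), 8), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            t_tests(np.array([2.0, 2.0, 2.0]))


class TestRMAnova:
    def test_constant_table_all_zero_ss(self):
        y = np.full((4, 3, 2), 5.0)
        res = rm_anova_two_way(y)
        for key in ("factor_a", "factor_b", "interaction"):
            assert res[key].extra["ss"] == pytest.approx(0.0)

    def test_ss_match_bruteforce_decomposition(self, rng):
        y = rng.normal(size=(4, 3, 2))
        res = rm_anova_two_way(y)
        ns, a, b = y.shape
        g = y.mean()
        # brute-force mean decomposition with explicit loops
        ss_a = sum(ns * b * (y[:, i, :].mean() - g) ** 2 for i in range(a))
        ss_b = sum(ns * a * (y[:, :, j].mean() - g) ** 2 for j in range(b))
        ss_ab = sum(
            ns * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + g) ** 2
            for i in range(a)
            for j in range(b)
        )
        assert res["factor_a"].extra["ss"] == pytest.approx(ss_a, abs=1e-10)
        assert res["factor_b"].extra["ss"] == pytest.approx(ss_b, abs=1e-10)
        assert res["interaction"].extra["ss"] == pytest.approx(ss_ab, abs=1e-10)

    def test_matches_pingouin_f_statistics(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=(6, 4, 2))
        rows = [
            {"participant": s, "factor_a": f"a{i}", "factor_b": f"b{j}", "value": y[s, i, j]}
            for s in range(6)
            for i in range(4)
            for j in range(2)
        ]
        df = pd.DataFrame(rows)
        res = rm_anova_two_way(df)
        ref = pg.rm_anova(data=df, dv="value", within=["factor_a", "factor_b"], subject="participant")
        assert res["factor_a"].statistic == pytest.approx(ref.loc[0, "F"], rel=1e-6)
        assert res["factor_b"].statistic == pytest.approx(ref.loc[1, "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(ref.loc[2, "F"], rel=1e-6)

    def test_planted_factor_a_effect_detected(self, rng):
        y = rng.normal(size=(7, 6, 2))
        y[:, 0, :] += 3.0  # one map responds much more strongly
        res = rm_anova_two_way(y)
        assert res["factor_a"].p < 0.001
        assert res["factor_b"].p > 0.01

    def test_bonferroni_pairwise_count_and_cap(self, rng):
        y = rng.normal(size=(5, 3, 2))
        res = rm_anova_two_way(y)
        assert len(res["pairwise_a"]) == 3
        assert all(0 <= p["p_bonf"] <= 1 for p in res["pairwise_a"])

    def test_unbalanced_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant": [0, 0, 0, 1, 1],
                "factor_a": ["a", "a", "b", "a", "a"],
                "factor_b": ["x", "y", "x", "x", "y"],
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        with pytest.raises(ValueError, match="nbalanced"):
            rm_anova_two_way(df)


class TestPearsonEffectiveN:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r = pearson_effective_n(x, x, 1.0)
        assert r.statistic == pytest.approx(1.0)

    def test_factor_one_matches_standard_pearson(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        ours = pearson_effective_n(x, y, 1.0)
        ref = sps.pearsonr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_upsampling_inflates_p_not_r(self, rng):
        x = rng.normal(size=40)
        y = x + 2 * rng.normal(size=40)
        r1 = pearson_effective_n(x, y, 1.0)
        r4 = pearson_effective_n(x, y, 4.0)
        assert r4.statistic == r1.statistic
        assert r4.p > r1.p

    def test_too_small_effective_n_rejected(self):
        with pytest.raises(ValueError, match="ffective"):
            pearson_effective_n(np.arange(4.0), np.arange(4.0), 2.0)


class TestRecoveryMetrics:
    def test_perfect_fits_have_zero_bias(self):
        from numtune.fitting import PRFFit
        from numtune.models import TuningModel
        from numtune.synth import GroundTruthVoxel

        truth = [
            GroundTruthVoxel(TuningModel("linear", m, 1.0), 2.0, 0.0, 0.1, i)
            for i, m in enumerate((2.0, 4.0, 6.0))
        ]
        fits = [PRFFit(t.tuning, 2.0, 0.0, 1.0) for t in truth]
        tab = recovery_metrics(truth, fits).set_index("parameter")
        assert tab.loc["mu", "bias"] == 0.0
        assert tab.loc["sigma", "rmse"] == 0.0
        assert tab.loc["beta", "rmse"] == 0.0

    def test_untuned_voxels_skipped(self):
        from numtune.synth import GroundTruthVoxel

        truth = [GroundTruthVoxel(None, 1.0, 0.0, 0.1, 0)]
        assert recovery_metrics(truth, [None]).empty
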