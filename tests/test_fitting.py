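"""Estimation: grid pRF fits vs brute-force oracle, GLM vs normal equations,
HRF recovery, exclusion rules, run averaging."""

import numpy as np
import pytest

from numtune.design import build_symbolic_run, symbolic_config
from numtune.fitting import (
    FitConfig,
    PredictionGrid,
    apply_exclusions,
    average_runs,
    default_fit_config,
    estimate_hrf,
    fit_glm,
    fit_prf,
    fit_prf_many,
    glm_design,
)
from numtune.models import HRFParams, TuningModel, predict_timecourse


class TestAverageRuns:
    def test_single_run_identity(self, rng):
        x = rng.normal(size=(3, 10, 1))
        assert np.array_equal(average_runs(x), x[:, :, 0])

    def test_opposite_runs_cancel(self, rng):
        x = rng.normal(size=(3, 10))
        assert np.allclose(average_runs(np.stack([x, -x], axis=-1)), 0.0)

    def test_noise_shrinks_by_sqrt_n(self, rng):
        x = rng.normal(size=(1, 2000, 16))
        avg = average_runs(x)
        assert avg.std() == pytest.approx(1 / 4, rel=0.10)

    def test_ragged_runs_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_runs([np.zeros((2, 5)), np.zeros((2, 6))])


class TestPRFFit:
    def test_noiseless_roundtrip_linear(self, symbolic_seq, hrf, linear_grid):
        true = TuningModel("linear", 3.0, 0.8)
        y = predict_timecourse(true, symbolic_seq, hrf, beta=2.0, baseline=10.0).tr_series
        cfg = default_fit_config("linear")
        f = fit_prf(y, symbolic_seq, hrf, cfg, "linear", linear_grid)
        assert f.model.mu == pytest.approx(3.0, abs=1e-3)
        assert f.model.sigma == pytest.approx(0.8, abs=1e-3)
        assert f.beta == pytest.approx(2.0, rel=1e-3)
        assert f.baseline == pytest.approx(10.0, abs=1e-2)

    def test_grid_only_recovers_within_one_step(self, symbolic_seq, hrf, linear_grid):
        cfg = default_fit_config("linear", refine=False)
        true_mu = 3.0
        y = predict_timecourse(TuningModel("linear", true_mu, 0.8), symbolic_seq, hrf).tr_series
        f = fit_prf(y, symbolic_seq, hrf, cfg, "linear", linear_grid)
        step = np.max(np.diff(cfg.mu_grid))
        assert abs(f.model.mu - true_mu) <= step

    def test_single_candidate_equal_to_truth(self, symbolic_seq, hrf):
        cfg = FitConfig(mu_grid=np.array([3.0]), sigma_grid=np.array([0.8]), refine=False)
        y = predict_timecourse(TuningModel("linear", 3.0, 0.8), symbolic_seq, hrf).tr_series
        f = fit_prf(y, symbolic_seq, hrf, cfg, "linear")
        assert f.r2 == pytest.approx(1.0, abs=1e-12)

    def test_grid_matches_bruteforce_oracle(self, symbolic_seq, hrf, rng):
        """Exhaustive vectorized grid equals a plain loop over all candidates
        with closed-form scale/offset."""
        cfg = FitConfig(
            mu_grid=np.linspace(1, 7, 7), sigma_grid=np.geomspace(0.3, 3, 5), refine=False
        )
        y = predict_timecourse(TuningModel("linear", 3.3, 0.9), symbolic_seq, hrf).tr_series
        y = y + rng.normal(0, 0.2, y.size)
        f = fit_prf(y, symbolic_seq, hrf, cfg, "linear")

        best = (np.inf, None)
        for mu in cfg.mu_grid:
            for sigma in cfg.sigma_grid:
                pred = predict_timecourse(TuningModel("linear", mu, sigma), symbolic_seq, hrf).tr_series
                X = np.column_stack([pred, np.ones_like(pred)])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ coef) ** 2))
                if rss < best[0] - 1e-12:
                    best = (rss, (mu, sigma, coef))
        mu_o, sigma_o, coef_o = best[1]
        assert f.model.mu == pytest.approx(mu_o)
        assert f.model.sigma == pytest.approx(sigma_o)
        assert f.beta == pytest.approx(coef_o[0], abs=1e-8)
        tss = np.sum((y - y.mean()) ** 2)
        assert f.r2 == pytest.approx(1 - best[0] / tss, abs=1e-10)

    def test_refinement_never_decreases_r2(self, symbolic_seq, hrf, linear_grid, rng):
        y = predict_timecourse(TuningModel("linear", 4.1, 1.3), symbolic_seq, hrf).tr_series
        y = y + rng.normal(0, 0.3, y.size)
        f_grid = fit_prf(y, symbolic_seq, hrf, default_fit_config("linear", refine=False), "linear", linear_grid)
        f_ref = fit_prf(y, symbolic_seq, hrf, default_fit_config("linear"), "linear", linear_grid)
        assert f_ref.r2 >= f_grid.r2 - 1e-12

    def test_constant_series_flagged_degenerate(self, symbolic_seq, hrf, linear_grid):
        f = fit_prf(np.full(symbolic_seq.n_trs_analyzed, 3.0), symbolic_seq, hrf,
                    default_fit_config("linear", refine=False), "linear", linear_grid)
        assert f.degenerate and f.r2 == 0.0 and f.beta == 0.0

    def test_nonfinite_series_rejected(self, symbolic_seq, hrf, linear_grid):
        y = np.zeros(symbolic_seq.n_trs_analyzed)
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_prf(y, symbolic_seq, hrf, default_fit_config("linear"), "linear", linear_grid)

    def test_pure_noise_low_insample_r2_on_long_series(self, hrf, rng):
        # against an independent noise series the tuning family explains ~0
        cfg_design = symbolic_config()
        seq = build_symbolic_run(cfg_design)
        cfg = default_fit_config("linear", refine=False)
        grid = PredictionGrid(seq, hrf, cfg, "linear")
        r2s = [
            fit_prf(rng.normal(size=seq.n_trs_analyzed), seq, hrf, cfg, "linear", grid).r2
            for _ in range(10)
        ]
        # in-sample overfitting over 3200 candidates stays modest on 176 TRs
        assert 0 < np.mean(r2s) < 0.15


class TestGLM:
    def test_small_fixture_matches_normal_equations(self, rng):
        X = np.column_stack([np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 0], float), np.ones(10)])
        y = rng.normal(size=10)
        g = fit_glm(y, X)
        beta_o = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_o
        s2 = resid @ resid / (10 - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        assert np.allclose(g.betas, beta_o, atol=1e-10)
        assert g.tvalue == pytest.approx(beta_o[0] / se, abs=1e-10)

    def test_perfect_fit_guarded_large_t(self, symbolic_seq, hrf):
        X = glm_design(symbolic_seq, hrf)
        g = fit_glm(X[:, 0] * 2.0 + 1.0, X)
        assert g.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(g.tvalue) and g.tvalue >= 1e6

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_glm(np.arange(10.0), X)

    def test_null_t_distribution(self, symbolic_seq, hrf, rng):
        X = glm_design(symbolic_seq, hrf)
        ts = [fit_glm(rng.normal(size=X.shape[0]), X).tvalue for _ in range(200)]
        # under the null t is centred with SD near 1
        assert abs(np.mean(ts)) < 0.25
        assert 0.8 < np.std(ts) < 1.3


class TestEstimateHRF:
    def test_recovers_shifted_peak_delay(self, symbolic_seq, hrf, linear_grid):
        hrf_true = HRFParams(peak_delay=7.0)
        mus = np.linspace(1.5, 6.5, 10)
        data = np.stack(
            [predict_timecourse(TuningModel("linear", m, 1.0), symbolic_seq, hrf_true).tr_series for m in mus]
        )
        cfg = default_fit_config("linear", refine=False)
        fits0 = fit_prf_many(data, symbolic_seq, hrf, cfg, "linear", linear_grid)
        est = estimate_hrf(data, fits0, symbolic_seq, cfg, "linear", hrf)
        assert est.peak_delay == pytest.approx(7.0, abs=0.25)

    def test_fixed_point_at_true_hrf(self, symbolic_seq, hrf, linear_grid):
        data = np.stack(
            [predict_timecourse(TuningModel("linear", m, 1.0), symbolic_seq, hrf).tr_series for m in (2.0, 4.0, 6.0)]
        )
        cfg = default_fit_config("linear", refine=False)
        fits0 = fit_prf_many(data, symbolic_seq, hrf, cfg, "linear", linear_grid)
        est = estimate_hrf(data, fits0, symbolic_seq, cfg, "linear", hrf)
        assert est.peak_delay == pytest.approx(hrf.peak_delay, abs=0.1)
        assert est.undershoot_ratio == pytest.approx(hrf.undershoot_ratio, abs=0.05)

    def test_refit_does_not_lower_mean_r2(self, symbolic_seq, hrf, linear_grid):
        hrf_true = HRFParams(peak_delay=7.0)
        data = np.stack(
            [predict_timecourse(TuningModel("linear", m, 1.0), symbolic_seq, hrf_true).tr_series for m in (2.0, 4.0, 6.0)]
        )
        cfg = default_fit_config("linear", refine=False)
        fits0 = fit_prf_many(data, symbolic_seq, hrf, cfg, "linear", linear_grid)
        est = estimate_hrf(data, fits0, symbolic_seq, cfg, "linear", hrf)
        grid2 = PredictionGrid(symbolic_seq, est, cfg, "linear")
        fits1 = fit_prf_many(data, symbolic_seq, est, cfg, "linear", grid2)
        assert np.mean([f.r2 for f in fits1]) >= np.mean([f.r2 for f in fits0]) - 1e-6

    def test_no_qualifying_voxels_errors(self, symbolic_seq, hrf, linear_grid, rng):
        data = rng.normal(size=(3, symbolic_seq.n_trs_analyzed))
        cfg = default_fit_config("linear", refine=False)
        fits0 = fit_prf_many(data, symbolic_seq, hrf, cfg, "linear", linear_grid)
        with pytest.raises(ValueError, match="threshold"):
            estimate_hrf(data, fits0, symbolic_seq, cfg, "linear", hrf)


class TestExclusions:
    def test_threshold_and_range_rule(self):
        cfg = default_fit_config("linear")

        def mk(mu, r2):
            return type("F", (), {"model": TuningModel("linear", mu, 1.0), "r2": r2})()

        fits = [mk(3.0, 0.29), mk(3.0, 0.31), mk(7.5, 0.90), mk(1.0, 0.30), mk(7.0, 0.95)]
        mask = apply_exclusions(fits, cfg)
        assert list(mask) == [False, True, False, True, True]

    def test_empty_input(self):
        assert apply_exclusions([], default_fit_config("linear")).size == 0
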