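"""Model estimation: pRF grid+refine fits, GLM contrasts, HRF refitting.

The pRF fit is an exhaustive search over a (mu, sigma) candidate grid.  For
each candidate the unit prediction is precomputed once per (sequence, HRF)
pair, and the amplitude/offset pair is solved in closed form by least
squares, so scanning thousands of candidates against a voxel costs one
matrix-vector product.  The grid optimum is optionally polished by a
derivative-free bounded local search.  Goodness of fit is variance explained
R^2 = 1 - RSS/TSS (offset fitted, not squared correlation), which permits
negative values under cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .design import StimulusSequence
from .models import (
    HRFParams,
    TuningModel,
    event_basis,
    neural_amplitudes,
    predict_batch,
    predict_from_amplitudes,
    untuned_amplitudes,
)

__all__ = [
    "FitConfig",
    "PRFFit",
    "GLMFit",
    "PredictionGrid",
    "default_fit_config",
    "average_runs",
    "fit_prf",
    "fit_prf_many",
    "fit_glm",
    "glm_design",
    "estimate_hrf",
    "apply_exclusions",
]

T_LARGE = 1e12  # stand-in for an infinite t statistic on a perfect fit


@dataclass(frozen=True)
class FitConfig:
    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    refine: bool = True
    r2_threshold: float = 0.30
    stimulus_range: tuple[float, float] = (1.0, 7.0)
    refine_tol: float = 1e-4

    def __post_init__(self) -> None:
        for name, g in (("mu_grid", self.mu_grid), ("sigma_grid", self.sigma_grid)):
            arr = np.asarray(g, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, arr)


def default_fit_config(space: str, **overrides) -> FitConfig:
    """Default candidate grids, wide enough that preferred values outside the
    presented range [1, 7] are attainable."""
    if space == "log":
        kw = dict(
            mu_grid=np.geomspace(0.5, 14.0, 80),
            sigma_grid=np.geomspace(0.05, 5.0, 40),
        )
    elif space == "linear":
        kw = dict(
            mu_grid=np.linspace(-1.0, 14.0, 80),
            sigma_grid=np.geomspace(0.1, 10.0, 40),
        )
    else:
        raise ValueError("space must be 'log' or 'linear'")
    kw.update(overrides)
    return FitConfig(**kw)


@dataclass
class PRFFit:
    model: TuningModel
    beta: float
    baseline: float
    r2: float
    degenerate: bool = False


@dataclass
class GLMFit:
    betas: np.ndarray
    tvalue: float
    r2: float
    df_resid: int


def average_runs(runs) -> np.ndarray:
    """Pointwise mean across runs of a voxels x TRs x runs array."""
    if isinstance(runs, (list, tuple)):
        lengths = {np.asarray(r).shape for r in runs}
        if len(lengths) > 1:
            raise ValueError(f"runs have mismatched shapes: {sorted(lengths)}")
        runs = np.stack([np.asarray(r) for r in runs], axis=-1)
    runs = np.asarray(runs, dtype=float)
    if runs.ndim != 3:
        raise ValueError("expected a voxels x TRs x runs array (or list of equal-shape runs)")
    if runs.shape[-1] < 1:
        raise ValueError("need at least one run")
    return runs.mean(axis=-1)


class PredictionGrid:
    """Unit predictions for every (mu, sigma) candidate of a grid.

    Candidates are ordered mu-major then sigma, both ascending, so that
    ``argmin`` over RSS realizes the smallest-mu-then-smallest-sigma
    tie-break deterministically.
    """

    def __init__(self, seq: StimulusSequence, hrf: HRFParams, cfg: FitConfig, space: str):
        if space == "log" and np.any(cfg.mu_grid <= 0):
            raise ValueError("log-space mu grid must be strictly positive")
        self.seq = seq
        self.hrf = hrf
        self.cfg = cfg
        self.space = space
        mus, sigmas = np.meshgrid(cfg.mu_grid, cfg.sigma_grid, indexing="ij")
        self.mus = mus.ravel()
        self.sigmas = sigmas.ravel()
        # batched tuning responses over the event train, then one batched
        # convolution for all candidates
        vals = np.array([e.value for e in seq.events], dtype=float)
        numeric = np.array([e.trial_type != "distractor" for e in seq.events])
        if space == "log":
            if np.any(vals[numeric] <= 0):
                raise ValueError("log-space fitting is undefined for stimulus magnitudes <= 0")
            z = (np.log(vals[None, :]) - np.log(self.mus[:, None])) / self.sigmas[:, None]
        else:
            z = (vals[None, :] - self.mus[:, None]) / self.sigmas[:, None]
        amps = np.exp(-0.5 * z**2) * numeric[None, :]
        self.basis = event_basis(seq, hrf)
        self._vals = vals
        self._numeric = numeric
        preds = predict_batch(amps, seq, hrf, self.basis)
        self.preds = preds
        self._pc = preds - preds.mean(axis=1, keepdims=True)
        self._pss = np.einsum("ij,ij->i", self._pc, self._pc)

    def unit_prediction(self, mu: float, sigma: float) -> np.ndarray:
        """Unit prediction for an off-grid candidate, via the cached basis."""
        if self.space == "log":
            z = (np.log(self._vals) - np.log(mu)) / sigma
        else:
            z = (self._vals - mu) / sigma
        return (np.exp(-0.5 * z**2) * self._numeric) @ self.basis


PSS_FLOOR = 1e-30  # below this a prediction is effectively constant


def _closed_form(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (beta, baseline, rss) for y ~ beta*pred + baseline.

    An (effectively) constant prediction is degenerate: beta is pinned to 0
    and the fit reduces to the offset alone.
    """
    pc = pred - pred.mean()
    yc = y - y.mean()
    pss = pc @ pc
    if pss <= PSS_FLOOR:
        return 0.0, float(y.mean()), float(yc @ yc)
    beta = float((pc @ yc) / pss)
    rss = float(yc @ yc - beta**2 * pss)
    return beta, float(y.mean() - beta * pred.mean()), max(rss, 0.0)


def fit_prf(
    ts: np.ndarray,
    seq: StimulusSequence,
    hrf: HRFParams,
    cfg: FitConfig,
    space: str = "log",
    grid: PredictionGrid | None = None,
) -> PRFFit:
    """Fit a Gaussian tuning model to one voxel's per-TR series."""
    return fit_prf_many(np.atleast_2d(np.asarray(ts, dtype=float)), seq, hrf, cfg, space, grid)[0]


def fit_prf_many(
    data: np.ndarray,
    seq: StimulusSequence,
    hrf: HRFParams,
    cfg: FitConfig,
    space: str = "log",
    grid: PredictionGrid | None = None,
) -> list[PRFFit]:
    """Vectorized grid fit of many voxels (voxels x TRs) against one grid."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != seq.n_trs_analyzed:
        raise ValueError("data must be voxels x n_trs_analyzed")
    if not np.all(np.isfinite(data)):
        raise ValueError("time series contain non-finite values")
    if grid is None:
        grid = PredictionGrid(seq, hrf, cfg, space)

    yc = data - data.mean(axis=1, keepdims=True)
    tss = np.einsum("vj,vj->v", yc, yc)
    # beta[c, v] for every candidate c and voxel v, then RSS = TSS - beta^2 * PSS
    num = grid._pc @ yc.T
    usable = grid._pss > PSS_FLOOR
    betas = np.zeros_like(num)
    betas[usable] = num[usable] / grid._pss[usable, None]
    rss = np.maximum(tss[None, :] - betas**2 * grid._pss[:, None], 0.0)

    fits: list[PRFFit] = []
    best = np.argmin(rss, axis=0)
    for v in range(data.shape[0]):
        y = data[v]
        if tss[v] <= 0:
            fits.append(
                PRFFit(
                    model=TuningModel(space, float(grid.mus[0]), float(grid.sigmas[0])),
                    beta=0.0,
                    baseline=float(y.mean()),
                    r2=0.0,
                    degenerate=True,
                )
            )
            continue
        c = int(best[v])
        mu, sigma = float(grid.mus[c]), float(grid.sigmas[c])
        beta = float(betas[c, v])
        rss_best = float(rss[c, v])
        baseline = float(y.mean() - beta * grid.preds[c].mean())

        if cfg.refine:
            mu, sigma, beta, baseline, rss_best = _refine(y, grid, cfg, mu, sigma, rss_best, beta, baseline)

        r2 = 1.0 - rss_best / tss[v]
        fits.append(PRFFit(model=TuningModel(space, mu, sigma), beta=beta, baseline=baseline, r2=float(r2)))
    return fits


def _refine(y, grid: PredictionGrid, cfg, mu0, sigma0, rss0, beta0, base0):
    """Bounded Nelder-Mead polish of the grid optimum; never returns worse."""
    lo_mu, hi_mu = cfg.mu_grid[0], cfg.mu_grid[-1]
    lo_s, hi_s = cfg.sigma_grid[0], cfg.sigma_grid[-1]

    def objective(x):
        mu, sigma = x
        if not (lo_mu <= mu <= hi_mu and lo_s <= sigma <= hi_s):
            return np.inf
        return _closed_form(grid.unit_prediction(mu, sigma), y)[2]

    res = minimize(
        objective,
        x0=[mu0, sigma0],
        method="Nelder-Mead",
        options={"xatol": cfg.refine_tol, "fatol": cfg.refine_tol * max(rss0, 1.0), "maxiter": 200},
    )
    if np.isfinite(res.fun) and res.fun <= rss0:
        mu, sigma = float(res.x[0]), float(res.x[1])
        beta, base, rss = _closed_form(grid.unit_prediction(mu, sigma), y)
        if rss <= rss0:
            return mu, sigma, beta, base, rss
    return mu0, sigma0, beta0, base0, rss0


def glm_design(seq: StimulusSequence, hrf: HRFParams) -> np.ndarray:
    """Design matrix [main-vs-baseline HRF-convolved regressor, intercept]."""
    reg = predict_from_amplitudes(untuned_amplitudes(seq), seq, hrf).tr_series
    return np.column_stack([reg, np.ones_like(reg)])


def fit_glm(ts: np.ndarray, design: np.ndarray) -> GLMFit:
    """OLS fit of a design (contrast regressor(s) + intercept); t for column 0.

    A perfect fit would give an infinite t; it is reported as a large finite
    value instead.
    """
    import statsmodels.api as sm

    y = np.asarray(ts, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be TRs x regressors matching the series length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    t0 = float(res.tvalues[0])
    if not np.isfinite(t0) or abs(t0) > T_LARGE:
        t0 = float(np.sign(beta[0]) * T_LARGE) if beta[0] != 0 else 0.0
    # R^2 as variance explained about the mean (matches the pRF definition)
    yc = y - y.mean()
    tss = float(yc @ yc)
    r2 = 1.0 - float(res.ssr) / tss if tss > 0 else 0.0
    return GLMFit(betas=beta, tvalue=t0, r2=float(r2), df_resid=int(res.df_resid))


def estimate_hrf(
    data: np.ndarray,
    initial_fits: list[PRFFit],
    seq: StimulusSequence,
    cfg: FitConfig,
    space: str = "log",
    initial_hrf: HRFParams | None = None,
) -> HRFParams:
    """Estimate participant-level HRF parameters from well-fit voxels.

    Holding each qualifying voxel's (mu, sigma) fixed, ``peak_delay`` and
    ``undershoot_ratio`` are optimized to maximize the summed variance
    explained (amplitude and offset re-solved in closed form per voxel).
    Only two HRF parameters are freed to avoid degeneracy with tuning width.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    hrf0 = initial_hrf or HRFParams()
    keep = [i for i, f in enumerate(initial_fits) if f.r2 >= cfg.r2_threshold and not f.degenerate]
    if not keep:
        raise ValueError(
            "no voxels pass the R^2 threshold with the initial HRF; "
            "relax cfg.r2_threshold or check the data"
        )
    models = [initial_fits[i].model for i in keep]
    series = data[keep]
    tss = np.array([float((y - y.mean()) @ (y - y.mean())) for y in series])
    amps = np.stack([neural_amplitudes(m, seq) for m in models])

    def neg_total_r2(x):
        delay, ratio = x
        if not (2.0 <= delay <= 12.0 and 0.0 <= ratio <= 1.0):
            return np.inf
        hrf = replace(hrf0, peak_delay=float(delay), undershoot_ratio=float(ratio))
        preds = amps @ event_basis(seq, hrf)
        total = 0.0
        for pred, y, t in zip(preds, series, tss):
            rss = _closed_form(pred, y)[2]
            total += 1.0 - rss / t
        return -total

    res = minimize(
        neg_total_r2,
        x0=[hrf0.peak_delay, hrf0.undershoot_ratio],
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200},
    )
    if np.isfinite(res.fun) and -res.fun >= -neg_total_r2([hrf0.peak_delay, hrf0.undershoot_ratio]):
        return replace(hrf0, peak_delay=float(res.x[0]), undershoot_ratio=float(res.x[1]))
    return hrf0


def apply_exclusions(fits: list[PRFFit], cfg: FitConfig) -> np.ndarray:
    """Keep voxels with R^2 >= threshold and preferred value inside the
    presented stimulus range (inclusive)."""
    lo, hi = cfg.stimulus_range
    return np.array(
        [(f.r2 >= cfg.r2_threshold) and (lo <= f.model.mu <= hi) for f in fits],
        dtype=bool,
    )
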