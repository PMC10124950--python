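"""Split-half cross-validated comparison of tuned (pRF) vs untuned (GLM) models.

Runs are split into odd and even halves.  Models are fitted to each half's
run-averaged series; the training-half prediction is then regressed (scale
and offset free, all other parameters frozen) onto the other half's averaged
series, and the variance explained in each direction is averaged per voxel.
Delta VE = VE_pRF - VE_GLM > 0 marks a site better explained by tuning than
by an untuned stimulus-driven response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StimulusSequence
from .fitting import (
    FitConfig,
    PredictionGrid,
    PRFFit,
    _closed_form,
    apply_exclusions,
    fit_prf_many,
    glm_design,
)
from .models import HRFParams, predict_timecourse

__all__ = ["CVResult", "split_half_cv", "proportion_tuned", "roi_average_timeseries", "roi_ve_summary"]


@dataclass
class CVResult:
    ve_prf: np.ndarray
    ve_glm: np.ndarray
    delta_ve: np.ndarray
    halves: str
    valid: np.ndarray  # passed exclusions in both halves
    fits_half: tuple[list[PRFFit], list[PRFFit]] | None = None


def _cv_r2(pred: np.ndarray, y: np.ndarray) -> float:
    """VE of a frozen prediction regressed (scale+offset) onto a test series."""
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        return 0.0
    rss = _closed_form(pred, y)[2]
    return 1.0 - rss / tss


def split_half_cv(
    runs: np.ndarray,
    seq: StimulusSequence,
    hrf: HRFParams,
    cfg: FitConfig,
    space: str = "linear",
    grid: PredictionGrid | None = None,
) -> CVResult:
    """Odd/even split-half cross-validation of pRF vs GLM per voxel."""
    runs = np.asarray(runs, dtype=float)
    if runs.ndim != 3:
        raise ValueError("expected voxels x TRs x runs")
    n_runs = runs.shape[2]
    if n_runs < 2:
        raise ValueError("split-half cross-validation needs at least 2 runs")
    odd = runs[:, :, 0::2].mean(axis=2)  # runs 1, 3, 5, ... (1-based)
    even = runs[:, :, 1::2].mean(axis=2)
    halves = (odd, even)
    if grid is None:
        grid = PredictionGrid(seq, hrf, cfg, space)
    X = glm_design(seq, hrf)
    glm_reg = X[:, 0]

    n_vox = runs.shape[0]
    fits = [fit_prf_many(h, seq, hrf, cfg, space, grid) for h in halves]
    ve_prf = np.zeros(n_vox)
    ve_glm = np.zeros(n_vox)
    for train in (0, 1):
        test = 1 - train
        for v in range(n_vox):
            prf_pred = predict_timecourse(fits[train][v].model, seq, hrf).tr_series
            ve_prf[v] += 0.5 * _cv_r2(prf_pred, halves[test][v])
            ve_glm[v] += 0.5 * _cv_r2(glm_reg, halves[test][v])
    valid = apply_exclusions(fits[0], cfg) & apply_exclusions(fits[1], cfg)
    return CVResult(
        ve_prf=ve_prf,
        ve_glm=ve_glm,
        delta_ve=ve_prf - ve_glm,
        halves=f"odd runs (n={odd.shape}) vs even runs; {n_runs} runs total",
        valid=valid,
        fits_half=(fits[0], fits[1]),
    )


def proportion_tuned(cv: CVResult, roi_mask: np.ndarray | None = None, require_valid: bool = True) -> float:
    """Fraction of ROI voxels whose activity is better explained by tuning.

    Ties (delta VE exactly 0) count as not-better.  With ``require_valid``
    (default) voxels failing the exclusion rule in either half are dropped.
    """
    if roi_mask is None:
        roi_mask = np.ones(cv.delta_ve.shape[0], dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("ROI is empty")
    keep = roi_mask & cv.valid if require_valid else roi_mask
    if keep.sum() == 0:
        raise ValueError("no ROI voxels pass the exclusion rule in both halves")
    return float(np.mean(cv.delta_ve[keep] > 0))


def roi_average_timeseries(data: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Pointwise mean series over the voxels of one ROI."""
    data = np.asarray(data, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("ROI is empty")
    return data[roi_mask].mean(axis=0)


def roi_ve_summary(values_per_participant) -> dict:
    """Mean and SD across participant-level ROI values.

    With a single participant the SD is undefined and reported as 0 with
    ``sd_defined=False``.
    """
    vals = np.asarray(list(values_per_participant), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one participant")
    if vals.size == 1:
        return {"mean": float(vals[0]), "sd": 0.0, "n": 1, "sd_defined": False}
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n": int(vals.size), "sd_defined": True}
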