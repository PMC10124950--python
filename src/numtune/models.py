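"""Forward encoding models: Gaussian tuning, HRF kernel, BOLD prediction.

A recording site's aggregate tuning is modelled as a one-dimensional Gaussian
over stimulus magnitude — in logarithmic magnitude space for nonsymbolic
numerosity (Weber-like compression) and in linear space for symbolic numbers.
The neural prediction for a run is a train of 300 ms boxcars, one per
presentation, scaled by the tuning response to the presented magnitude;
convolving with a hemodynamic response function and averaging within TR
intervals yields the predicted BOLD series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import fftconvolve

from .design import StimulusSequence

__all__ = [
    "TuningModel",
    "HRFParams",
    "Prediction",
    "tuning_response",
    "hrf_kernel",
    "predict_timecourse",
    "neural_amplitudes",
    "untuned_amplitudes",
    "predict_from_amplitudes",
    "predict_batch",
]

FINE_DT = 0.05  # s; divides the 300 ms stimulus duration and 650 ms SOA exactly


@dataclass(frozen=True)
class TuningModel:
    """Gaussian tuning over stimulus magnitude.

    ``sigma`` is in natural-log units for ``space='log'`` and in stimulus
    units for ``space='linear'``.
    """

    space: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.space not in ("log", "linear"):
            raise ValueError("space must be 'log' or 'linear'")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.space == "log" and not self.mu > 0:
            raise ValueError("log-space tuning requires mu > 0")

    def response(self, s):
        return tuning_response(self, s)


def tuning_response(model: TuningModel, s) -> np.ndarray | float:
    """Unit-peak Gaussian tuning response at magnitude(s) ``s``.

    log:    exp(-(ln s - ln mu)^2 / (2 sigma^2)),  s > 0 required
    linear: exp(-(s - mu)^2 / (2 sigma^2))
    """
    s_arr = np.asarray(s, dtype=float)
    if model.space == "log":
        if np.any(s_arr <= 0):
            raise ValueError("log-space tuning is undefined for magnitudes <= 0")
        z = (np.log(s_arr) - np.log(model.mu)) / model.sigma
    else:
        z = (s_arr - model.mu) / model.sigma
    out = np.exp(-0.5 * z**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HRFParams:
    """Difference-of-two-gamma-densities hemodynamic response function.

    The positive lobe peaks at ``peak_delay`` seconds and the undershoot at
    ``undershoot_delay``; ``undershoot_ratio`` scales the undershoot relative
    to the peak lobe.  The sampled kernel is normalized to peak amplitude 1,
    so the overall response scale lives in the fit's beta.
    """

    peak_delay: float = 6.0
    peak_dispersion: float = 1.0
    undershoot_delay: float = 16.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")
        if self.kernel_length <= 0:
            raise ValueError("kernel_length must be positive")


def hrf_kernel(params: HRFParams, dt: float = FINE_DT) -> np.ndarray:
    """Sample the HRF kernel on [0, kernel_length] at resolution ``dt``.

    Each lobe is a gamma density parameterized so its mode sits at the stated
    delay (shape = 1 + delay/dispersion, scale = dispersion); the kernel is
    peak-normalized to 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.kernel_length + dt / 2, dt)
    peak = sps.gamma.pdf(t, a=1 + params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion)
    under = sps.gamma.pdf(
        t, a=1 + params.undershoot_delay / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    k = peak - params.undershoot_ratio * under
    return k / np.max(k)


@dataclass
class Prediction:
    """Predicted response: fine-grid neural+BOLD signal and the per-TR series."""

    fine_grid: np.ndarray
    tr_series: np.ndarray
    beta: float
    baseline: float


def _check_grid(cfg) -> tuple[int, int]:
    steps_per_tr = cfg.tr / FINE_DT
    steps_per_stim = cfg.stim_duration / FINE_DT
    if abs(steps_per_tr - round(steps_per_tr)) > 1e-9 or abs(steps_per_stim - round(steps_per_stim)) > 1e-9:
        raise ValueError(f"tr and stim_duration must be multiples of the fine grid dt = {FINE_DT}")
    return round(steps_per_tr), round(steps_per_stim)


def neural_amplitudes(model: TuningModel, seq: StimulusSequence) -> np.ndarray:
    """Per-presentation neural amplitude under a tuning model.

    Letter distractors carry no numerical magnitude and contribute zero.
    """
    amps = np.zeros(len(seq.events))
    for i, e in enumerate(seq.events):
        if e.trial_type == "distractor":
            continue
        amps[i] = tuning_response(model, e.value)
    return amps


def untuned_amplitudes(seq: StimulusSequence) -> np.ndarray:
    """Per-presentation amplitude of an untuned stimulus-driven site.

    Responds with unit amplitude to every non-baseline presentation and not
    at all to the baseline stimulus; this is the generative counterpart of
    the GLM's main-versus-baseline regressor.
    """
    base = seq.config.baseline_value
    amps = np.zeros(len(seq.events))
    for i, e in enumerate(seq.events):
        if e.trial_type == "distractor":
            continue
        amps[i] = 1.0 if e.value != base else 0.0
    return amps


def _fine_signal(amps: np.ndarray, seq: StimulusSequence) -> np.ndarray:
    """Fine-grid neural signal(s) from per-presentation amplitudes.

    ``amps`` may be (n_events,) or (batch, n_events); returns matching
    (n_fine,) or (batch, n_fine).  Presentations never overlap (SOA >=
    stimulus duration), so scattered assignment is safe.
    """
    cfg = seq.config
    steps_per_tr, steps_per_stim = _check_grid(cfg)
    n_fine = seq.n_trs_analyzed * steps_per_tr
    amps2 = np.atleast_2d(np.asarray(amps, dtype=float))
    neural = np.zeros((amps2.shape[0], n_fine))
    i0 = np.array([int(round(e.onset / FINE_DT)) for e in seq.events])
    for j in range(steps_per_stim):
        idx = i0 + j
        ok = idx < n_fine
        neural[:, idx[ok]] += amps2[:, ok]
    return neural if np.ndim(amps) == 2 else neural[0]


def event_basis(seq: StimulusSequence, hrf: HRFParams) -> np.ndarray:
    """Per-TR unit response of each presentation (n_events x n_TRs).

    Convolution followed by within-TR averaging is linear in the
    per-presentation amplitudes, so any prediction is ``amps @ basis``.
    Presentations share one fine-grid response shape; only its alignment
    within the TR differs, and there are at most tr/gcd(soa, tr) distinct
    phases, so the basis costs a handful of reshapes.
    """
    steps_per_tr, steps_per_stim = _check_grid(seq.config)
    n_tr = seq.n_trs_analyzed
    kernel = hrf_kernel(hrf, FINE_DT)
    r = fftconvolve(np.ones(steps_per_stim), kernel) * FINE_DT
    basis = np.zeros((len(seq.events), n_tr))
    phase_cache: dict[int, np.ndarray] = {}
    for i, e in enumerate(seq.events):
        i0 = int(round(e.onset / FINE_DT))
        k0, p = divmod(i0, steps_per_tr)
        if p not in phase_cache:
            padded = np.concatenate([np.zeros(p), r])
            n_k = -(-padded.size // steps_per_tr)
            padded = np.pad(padded, (0, n_k * steps_per_tr - padded.size))
            phase_cache[p] = padded.reshape(n_k, steps_per_tr).mean(axis=1)
        w = phase_cache[p]
        end = min(k0 + w.size, n_tr)
        if end > k0:
            basis[i, k0:end] += w[: end - k0]
    return basis


def predict_batch(
    amps: np.ndarray, seq: StimulusSequence, hrf: HRFParams, basis: np.ndarray | None = None
) -> np.ndarray:
    """Per-TR unit predictions for a batch of amplitude vectors (batch x TRs)."""
    if basis is None:
        basis = event_basis(seq, hrf)
    return np.atleast_2d(np.asarray(amps, dtype=float)) @ basis


def predict_from_amplitudes(
    amps: np.ndarray,
    seq: StimulusSequence,
    hrf: HRFParams,
    beta: float = 1.0,
    baseline: float = 0.0,
) -> Prediction:
    """HRF-convolved per-TR prediction from per-presentation neural amplitudes."""
    steps_per_tr, _ = _check_grid(seq.config)
    neural = _fine_signal(amps, seq)
    kernel = hrf_kernel(hrf, FINE_DT)
    n_fine = neural.shape[-1]
    bold = fftconvolve(neural, kernel)[:n_fine] * FINE_DT
    tr_series = bold.reshape(seq.n_trs_analyzed, steps_per_tr).mean(axis=1)
    return Prediction(
        fine_grid=baseline + beta * bold,
        tr_series=baseline + beta * tr_series,
        beta=beta,
        baseline=baseline,
    )


def predict_timecourse(
    model: TuningModel,
    seq: StimulusSequence,
    hrf: HRFParams,
    beta: float = 1.0,
    baseline: float = 0.0,
) -> Prediction:
    """Predicted BOLD time course of a tuned site for one run."""
    return predict_from_amplitudes(neural_amplitudes(model, seq), seq, hrf, beta, baseline)
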