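"""Ground-truth-known synthetic data: topographic voxel maps and behavior.

The generator emulates the statistical structure the analysis assumes: a 1-D
cortical sheet along which preferred magnitude changes gradually, voxels with
Gaussian tuning (log or linear space) whose HRF-convolved responses are
sampled at the TR, optional untuned stimulus-driven voxels, additive Gaussian
noise (i.i.d. or AR(1)), and a behavioral responder with configurable hit and
false-alarm probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import StimulusSequence
from .models import (
    HRFParams,
    TuningModel,
    neural_amplitudes,
    predict_from_amplitudes,
    untuned_amplitudes,
)

__all__ = [
    "NoiseConfig",
    "BehaviorConfig",
    "GroundTruthVoxel",
    "SyntheticDataset",
    "simulate_map",
    "simulate_untuned_voxel",
    "simulate_behavior",
]

DEFAULT_N_RUNS = 16  # typical number of functional runs per participant


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise per TR: Gaussian, optionally AR(1) with coefficient rho
    (stationary marginal SD kept equal to ``sd``)."""

    sd: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not -1 < self.rho < 1:
            raise ValueError("AR(1) rho must lie in (-1, 1)")


@dataclass(frozen=True)
class BehaviorConfig:
    p_hit_embedded: float = 0.94
    p_hit_catch: float = 0.84
    p_fa_distractor: float = 0.05
    rt_mean: float = 0.6
    rt_sd: float = 0.15

    def __post_init__(self) -> None:
        for p in (self.p_hit_embedded, self.p_hit_catch, self.p_fa_distractor):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rt_mean <= 0:
            raise ValueError("rt_mean must be positive")


@dataclass
class GroundTruthVoxel:
    tuning: TuningModel | None  # None marks an untuned stimulus-driven voxel
    amplitude: float
    offset: float
    noise_sd: float
    position: int


@dataclass
class SyntheticDataset:
    data: np.ndarray  # voxels x TRs x runs
    truth: list[GroundTruthVoxel]
    sequence: StimulusSequence
    hrf: HRFParams
    roi_labels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.roi_labels is None:
            self.roi_labels = np.zeros(self.data.shape[0], dtype=int)
        if len(self.truth) != self.data.shape[0]:
            raise ValueError("truth length must equal voxel count")


def _noise(rng: np.random.Generator, shape: tuple, noise: NoiseConfig) -> np.ndarray:
    if noise.sd == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, noise.sd, size=shape)
    if noise.rho == 0:
        return eps
    # innovation SD scaled so the stationary marginal SD equals noise.sd
    out = np.empty(shape)
    out[..., 0] = eps[..., 0]
    innov_scale = np.sqrt(1 - noise.rho**2)
    for t in range(1, shape[-1]):
        out[..., t] = noise.rho * out[..., t - 1] + innov_scale * eps[..., t]
    return out


def simulate_map(
    n_voxels: int,
    preference_range: tuple[float, float],
    sequence: StimulusSequence,
    hrf: HRFParams | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    space: str = "log",
    sigma: float = 0.5,
    amplitude: float = 1.0,
    offset: float = 0.0,
    n_runs: int = DEFAULT_N_RUNS,
    untuned_fraction: float = 0.0,
) -> SyntheticDataset:
    """Simulate a 1-D topographic map of tuned voxels.

    Preferred magnitudes are laid out monotonically along the sheet
    (log-spaced for log-space models, evenly spaced otherwise).  With
    ``untuned_fraction > 0`` the last voxels of the sheet are untuned
    stimulus-driven sites with matched response scale.  Each voxel's series
    is its noiseless HRF-convolved prediction plus seeded additive noise,
    drawn independently per run; runs share the stimulus sequence.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    lo, hi = preference_range
    if space == "log" and lo <= 0:
        raise ValueError("log-space preferences require a strictly positive range")
    if not hi >= lo:
        raise ValueError("preference_range must be ordered")
    hrf = hrf or HRFParams()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    n_untuned = int(round(untuned_fraction * n_voxels))
    n_tuned = n_voxels - n_untuned
    if space == "log":
        prefs = np.geomspace(lo, hi, n_tuned) if n_tuned > 1 else np.array([lo] * n_tuned)
    else:
        prefs = np.linspace(lo, hi, n_tuned) if n_tuned > 1 else np.array([lo] * n_tuned)

    truth: list[GroundTruthVoxel] = []
    data = np.empty((n_voxels, sequence.n_trs_analyzed, n_runs))
    for v in range(n_voxels):
        if v < n_tuned:
            tuning = TuningModel(space, float(prefs[v]), sigma)
            amps = neural_amplitudes(tuning, sequence)
        else:
            tuning = None
            amps = untuned_amplitudes(sequence)
        clean = predict_from_amplitudes(amps, sequence, hrf, beta=amplitude, baseline=offset).tr_series
        data[v] = clean[:, None] + _noise(rng, (n_runs, sequence.n_trs_analyzed), noise).T
        truth.append(
            GroundTruthVoxel(
                tuning=tuning, amplitude=amplitude, offset=offset, noise_sd=noise.sd, position=v
            )
        )
    return SyntheticDataset(data=data, truth=truth, sequence=sequence, hrf=hrf)


def simulate_untuned_voxel(
    sequence: StimulusSequence,
    hrf: HRFParams | None = None,
    amplitude: float = 1.0,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    n_runs: int = 1,
    offset: float = 0.0,
) -> np.ndarray:
    """One untuned stimulus-driven voxel: unit response to every non-baseline
    presentation, HRF-convolved.  Returns TRs (n_runs=1) or TRs x runs."""
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    hrf = hrf or HRFParams()
    noise = noise or NoiseConfig(sd=0.0)
    rng = np.random.default_rng(seed)
    clean = predict_from_amplitudes(
        untuned_amplitudes(sequence), sequence, hrf, beta=amplitude, baseline=offset
    ).tr_series
    out = clean[:, None] + _noise(rng, (n_runs, sequence.n_trs_analyzed), noise).T
    return out[:, 0] if n_runs == 1 else out


def simulate_behavior(
    sequence: StimulusSequence, cfg: BehaviorConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Simulate button presses for one run's labeled task trials.

    Embedded and catch targets are answered with their class hit probability
    at a latency drawn from Normal(rt_mean, rt_sd) truncated positive;
    distractors elicit a press with the false-alarm probability.  Returns the
    sorted response times (seconds from run start).
    """
    cfg = cfg or BehaviorConfig()
    rng = np.random.default_rng(seed)
    times: list[float] = []
    for e in sequence.events:
        if e.trial_type == "embedded_target":
            p = cfg.p_hit_embedded
        elif e.trial_type == "catch_target":
            p = cfg.p_hit_catch
        elif e.trial_type == "distractor":
            p = cfg.p_fa_distractor
        else:
            continue
        if rng.random() < p:
            rt = rng.normal(cfg.rt_mean, cfg.rt_sd)
            while rt <= 0:
                rt = rng.normal(cfg.rt_mean, cfg.rt_sd)
            times.append(e.onset + rt)
    return np.array(sorted(times))
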