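"""Construction of block-design stimulus sequences.

Both experiments use the same temporal skeleton: short visual presentations
(300 ms on, stimulus-onset asynchrony 650 ms) grouped into blocks of six
repeats of the same magnitude (3.9 s = 2 TRs at TR = 1.95 s).  One cycle is
an ascending sweep through the main values (1..7), a long baseline block
(15.6 s = 8 TRs), the descending sweep, and a second baseline block; four
cycles make one functional run of 182 TRs (354.9 s) of which the first six
TRs are dummies discarded from analysis.

The numerosity localizer uses dot patterns with baseline numerosity 20 and a
white-dot attention task; the symbolic-number run uses Arabic digits with
baseline digit 0 and a number-detection task (embedded +1 increments, random
catch increments, and morphologically similar letter distractors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DesignConfig",
    "PresentationEvent",
    "StimulusSequence",
    "build_numerosity_run",
    "build_symbolic_run",
    "inject_task_trials",
    "sequence_to_tr_design",
    "localizer_config",
    "symbolic_config",
]

TRIAL_TYPES = ("main", "embedded_target", "catch_target", "distractor", "white_dot_target")
SPECIAL_TYPES = ("embedded_target", "catch_target", "distractor", "white_dot_target")


@dataclass(frozen=True)
class DesignConfig:
    """Timing and task parameters of one run."""

    tr: float = 1.95
    soa: float = 0.65
    stim_duration: float = 0.30
    reps_per_value: int = 6
    n_cycles: int = 4
    main_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    baseline_value: int = 20
    baseline_reps: int = 24
    dummy_trs: int = 6
    task_rate: float = 0.10
    distractor_set: tuple[str, ...] = ("L", "Z", "E", "A", "S", "G", "T", "B")

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.soa < self.stim_duration:
            raise ValueError("soa must be at least stim_duration")
        if not self.main_values:
            raise ValueError("main_values must be non-empty")
        for name, reps in (("reps_per_value", self.reps_per_value), ("baseline_reps", self.baseline_reps)):
            dur = reps * self.soa
            n = dur / self.tr
            if reps and abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name} * soa = {dur:.4f} s is not an integer number of TRs "
                    f"(TR = {self.tr} s); block boundaries must be TR-aligned"
                )

    @property
    def trs_per_value(self) -> int:
        return round(self.reps_per_value * self.soa / self.tr)

    @property
    def trs_per_baseline(self) -> int:
        return round(self.baseline_reps * self.soa / self.tr)

    @property
    def trs_per_cycle(self) -> int:
        n_main = len(self.main_values) * self.trs_per_value
        return 2 * n_main + 2 * self.trs_per_baseline

    @property
    def n_trs_analyzed(self) -> int:
        return self.n_cycles * self.trs_per_cycle

    @property
    def n_trs_total(self) -> int:
        return self.n_trs_analyzed + self.dummy_trs


def localizer_config(**overrides) -> DesignConfig:
    """Default numerosity-localizer configuration (dots, baseline 20)."""
    return DesignConfig(**{"baseline_value": 20, "task_rate": 0.10, **overrides})


def symbolic_config(**overrides) -> DesignConfig:
    """Default symbolic-number configuration (digits, baseline 0)."""
    return DesignConfig(**{"baseline_value": 0, "task_rate": 0.20, **overrides})


@dataclass(frozen=True)
class PresentationEvent:
    onset: float
    duration: float
    value: int
    trial_type: str
    symbol: str

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")


@dataclass
class StimulusSequence:
    """One run: timed presentation events plus the per-TR magnitude vector.

    Time origin is the first analyzed TR; the dummy TRs are counted in
    ``n_trs_total`` but carry no events and no entries in ``tr_values``.
    """

    events: list[PresentationEvent]
    tr_values: np.ndarray
    n_trs_total: int
    n_trs_analyzed: int
    config: DesignConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_presentations(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """Total run duration in seconds, dummies included."""
        return self.n_trs_total * self.config.tr

    def validate(self) -> None:
        onsets = np.array([e.onset for e in self.events])
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(self.tr_values) != self.n_trs_analyzed:
            raise ValueError("tr_values length must equal n_trs_analyzed")


def _block_values(cfg: DesignConfig) -> list[tuple[int, int]]:
    """(value, n_presentations) blocks for one full run, in order."""
    asc = [(v, cfg.reps_per_value) for v in cfg.main_values]
    desc = [(v, cfg.reps_per_value) for v in reversed(cfg.main_values)]
    base = [(cfg.baseline_value, cfg.baseline_reps)] if cfg.baseline_reps else []
    cycle = asc + base + desc + base
    return cycle * cfg.n_cycles


def _build_run(cfg: DesignConfig, label_embedded: bool) -> StimulusSequence:
    events: list[PresentationEvent] = []
    tr_values: list[int] = []
    t = 0.0
    prev_value = cfg.baseline_value  # dummy period shows the baseline stimulus
    for value, reps in _block_values(cfg):
        for rep in range(reps):
            trial_type = "main"
            # +1 steps only occur entering/within the ascending limb, so this
            # labels exactly len(main_values) embedded targets per cycle.
            if label_embedded and rep == 0 and value == prev_value + 1:
                trial_type = "embedded_target"
            events.append(
                PresentationEvent(
                    onset=round(t, 10),
                    duration=cfg.stim_duration,
                    value=value,
                    trial_type=trial_type,
                    symbol=str(value),
                )
            )
            t += cfg.soa
            prev_value = value
        n_trs = round(reps * cfg.soa / cfg.tr)
        tr_values.extend([value] * n_trs)

    seq = StimulusSequence(
        events=events,
        tr_values=np.asarray(tr_values),
        n_trs_total=cfg.n_trs_total,
        n_trs_analyzed=cfg.n_trs_analyzed,
        config=cfg,
        metadata={"experiment": "symbolic" if label_embedded else "localizer"},
    )
    seq.validate()
    return seq


def build_numerosity_run(cfg: DesignConfig | None = None) -> StimulusSequence:
    """Numerosity localizer run: dots 1-7 ascending/descending, baseline 20 dots.

    The baseline numerosity is a real stimulus magnitude that enters the
    forward model, not a rest condition.
    """
    cfg = localizer_config() if cfg is None else cfg
    return _build_run(cfg, label_embedded=False)


def build_symbolic_run(cfg: DesignConfig | None = None) -> StimulusSequence:
    """Symbolic-number run: digits 1-7 with baseline digit 0.

    Embedded targets (+1 increments within the ascending limb, including the
    0-to-1 step out of baseline) are labeled deterministically; there are
    exactly seven per cycle.
    """
    cfg = symbolic_config() if cfg is None else cfg
    if cfg.baseline_value != 0:
        cfg = replace(cfg, baseline_value=0)
    return _build_run(cfg, label_embedded=True)


def inject_task_trials(seq: StimulusSequence, cfg: DesignConfig | None = None, seed: int = 0) -> StimulusSequence:
    """Insert task trials at seeded random positions, replacing main presentations.

    For the symbolic run: catch targets (a digit one larger than the previous
    presentation) and letter distractors (morphologically similar to the digit
    a catch would have shown), together ``task_rate`` of all presentations,
    split as evenly as possible.  For the localizer: white-dot targets at
    ``task_rate``.  Special trials are never placed adjacent to another
    special trial.  The realized count is ``round(task_rate * n)`` and is
    recorded in ``metadata``.
    """
    cfg = seq.config if cfg is None else cfg
    if not 0 <= cfg.task_rate < 1:
        raise ValueError("task_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    events = list(seq.events)
    n = len(events)
    n_task = round(cfg.task_rate * n)
    localizer = seq.metadata.get("experiment") == "localizer"

    special = np.array([e.trial_type != "main" for e in events])
    order = rng.permutation(n)
    chosen: list[int] = []
    blocked = special.copy()
    for i in order:
        if len(chosen) == n_task:
            break
        if i == 0 or blocked[i] or (i > 0 and blocked[i - 1]) or (i + 1 < n and blocked[i + 1]):
            continue
        chosen.append(i)
        blocked[i] = True
    if len(chosen) < n_task:
        raise ValueError(
            f"could only place {len(chosen)} of {n_task} task trials under the "
            "non-adjacency constraint; lower task_rate"
        )
    chosen_arr = np.sort(np.array(chosen, dtype=int))

    if localizer:
        for i in chosen_arr:
            e = events[i]
            events[i] = replace(e, trial_type="white_dot_target")
        counts = {"white_dot_target": int(len(chosen_arr))}
    else:
        kinds = np.array(["catch_target"] * (n_task // 2) + ["distractor"] * (n_task - n_task // 2))
        rng.shuffle(kinds)
        for i, kind in zip(chosen_arr, kinds):
            e = events[i]
            target = seq.events[i - 1].value + 1  # +1 over the previously shown digit
            if kind == "catch_target":
                events[i] = replace(e, trial_type="catch_target", value=target, symbol=str(target))
            else:
                letter_idx = min(target, len(cfg.distractor_set)) - 1
                events[i] = replace(e, trial_type="distractor", symbol=cfg.distractor_set[letter_idx])
        counts = {
            "catch_target": int(np.sum(kinds == "catch_target")),
            "distractor": int(np.sum(kinds == "distractor")),
        }

    meta = dict(seq.metadata)
    meta.update(
        task_seed=seed,
        requested_task_rate=cfg.task_rate,
        n_task_trials=n_task,
        achieved_task_rate=n_task / n if n else 0.0,
        task_counts=counts,
    )
    out = StimulusSequence(
        events=events,
        tr_values=seq.tr_values.copy(),
        n_trs_total=seq.n_trs_total,
        n_trs_analyzed=seq.n_trs_analyzed,
        config=cfg,
        metadata=meta,
    )
    out.validate()
    return out


def sequence_to_tr_design(seq: StimulusSequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-TR value vector and one-hot indicator matrix.

    Returns ``(values, indicators, levels)`` where ``indicators`` has one
    column per distinct magnitude (sorted ascending) and the columns
    partition the analyzed TRs.
    """
    values = np.asarray(seq.tr_values)
    if values.size == 0:
        return values, np.zeros((0, 0)), np.array([])
    levels = np.unique(values)
    indicators = (values[:, None] == levels[None, :]).astype(float)
    return values, indicators, levels
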