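"""Readers and writers: NIfTI volumes, BIDS-style events tables, configs.

Voxel data are handled as voxels x TRs x runs arrays.  On disk a dataset is
a 4D NIfTI with voxels along the first spatial axis and runs concatenated on
the time axis; the run structure and the TR are recorded in the header so a
round trip is lossless.  Events travel as tab-separated tables with columns
onset, duration, value, trial_type, symbol (seconds, 0-based time).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import DesignConfig, PresentationEvent, StimulusSequence

__all__ = [
    "write_bold",
    "read_bold",
    "write_events",
    "read_events",
    "sequence_from_events",
    "load_config",
    "save_config",
]

EVENT_COLUMNS = ["onset", "duration", "value", "trial_type", "symbol"]


def write_bold(path, data: np.ndarray, tr: float = 1.95) -> None:
    """Write a voxels x TRs x runs array (or voxels x TRs) to NIfTI or TSV."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("expected voxels x TRs (x runs)")
    v, t, r = data.shape
    if path.suffix == ".tsv":
        if r != 1:
            raise ValueError("TSV export holds a single run; use NIfTI for multi-run data")
        pd.DataFrame(data[:, :, 0]).to_csv(path, sep="\t", header=False, index=False)
        return
    # runs concatenated on the 4th (time) axis, voxels on the first spatial axis
    vol = np.transpose(data, (0, 2, 1)).reshape(v, 1, 1, r * t, order="C")
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    img.header["descrip"] = f"numtune runs={r} trs={t}".encode()
    nib.save(img, str(path))


def read_bold(path, expected_tr: float | None = None, n_runs: int | None = None) -> np.ndarray:
    """Read voxel data back as voxels x TRs x runs.

    If the header TR disagrees with ``expected_tr`` by more than 1 ms a
    warning is issued and the configured value takes precedence.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        arr = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=np.float32)
        return arr[:, :, None]
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj, dtype=np.float32)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume")
    header_tr = float(img.header.get_zooms()[3])
    if expected_tr is not None and abs(header_tr - expected_tr) > 1e-3:
        warnings.warn(
            f"{path}: header TR {header_tr:.4f} s differs from configured "
            f"{expected_tr:.4f} s; using the configured value",
            stacklevel=2,
        )
    descrip = img.header["descrip"].tobytes().decode(errors="ignore")
    runs = n_runs
    if runs is None:
        for tok in descrip.replace("\x00", " ").split():
            if tok.startswith("runs="):
                runs = int(tok.split("=")[1])
    if runs is None:
        runs = 1
    v = vol.shape[0]
    total_t = vol.shape[3]
    if total_t % runs:
        raise ValueError(f"{path}: {total_t} volumes do not divide into {runs} runs")
    t = total_t // runs
    return np.transpose(vol.reshape(v, runs, t), (0, 2, 1))


def write_events(path, events: list[PresentationEvent] | StimulusSequence) -> None:
    ev = events.events if isinstance(events, StimulusSequence) else events
    df = pd.DataFrame(
        [
            {"onset": e.onset, "duration": e.duration, "value": e.value, "trial_type": e.trial_type, "symbol": e.symbol}
            for e in ev
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(path) -> list[PresentationEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing events columns {sorted(missing)}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(onsets < 0):
        raise ValueError(f"{path}: negative onsets are not allowed")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: onsets must be strictly increasing")
    return [
        PresentationEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            value=int(r.value),
            trial_type=str(r.trial_type),
            symbol=str(r.symbol),
        )
        for r in df.itertuples()
    ]


def sequence_from_events(events: list[PresentationEvent], cfg: DesignConfig) -> StimulusSequence:
    """Rebuild a StimulusSequence (per-TR values included) from an events list."""
    tr_values = []
    n_per_tr = round(cfg.tr / cfg.soa)
    for k in range(cfg.n_trs_analyzed):
        idx = k * n_per_tr
        if idx >= len(events):
            raise ValueError("events do not cover the configured number of TRs")
        e = events[idx]
        # use the block value: special trials replaced a main presentation
        val = e.value if e.trial_type in ("main", "white_dot_target") else None
        if val is None:
            for e2 in events[idx : idx + n_per_tr]:
                if e2.trial_type in ("main", "white_dot_target"):
                    val = e2.value
                    break
        if val is None:
            val = e.value
        tr_values.append(val)
    seq = StimulusSequence(
        events=list(events),
        tr_values=np.asarray(tr_values),
        n_trs_total=cfg.n_trs_total,
        n_trs_analyzed=cfg.n_trs_analyzed,
        config=cfg,
        metadata={"source": "events_file"},
    )
    seq.validate()
    return seq


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
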