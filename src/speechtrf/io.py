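"""Serialization: trial containers (.npz + JSON sidecar), envelope text
series, TRF coefficient tables, and delimited result tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EnvelopeSeries, EEGRecording, LagGrid, TRFSet
from .simulate import SyntheticTrial

__all__ = [
    "write_trials",
    "read_trials",
    "write_envelope",
    "read_envelope",
    "write_trf_table",
    "read_trf_table",
]


def _trial_key(t: SyntheticTrial) -> str:
    return f"s{t.subject:03d}_{t.condition}_t{t.trial:03d}"


def write_trials(trials: Sequence[SyntheticTrial], path: str | Path) -> Path:
    """Write trials to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for t in trials:
        key = _trial_key(t)
        arrays[f"{key}__observed"] = t.observed_eeg.data
        arrays[f"{key}__clean"] = t.clean_eeg.data
        arrays[f"{key}__target"] = t.target_env.data
        arrays[f"{key}__masker"] = t.masker_env.data
        meta[key] = {
            "subject": t.subject,
            "trial": t.trial,
            "condition": t.condition,
            "fs": t.observed_eeg.fs,
            "channel_names": list(t.observed_eeg.channel_names),
        }
    npz_path = path.with_suffix(".npz")
    np.savez_compressed(npz_path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return npz_path


def read_trials(path: str | Path) -> list[SyntheticTrial]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    trials = []
    with np.load(path.with_suffix(".npz")) as npz:
        for key in sorted(meta):
            m = meta[key]
            fs = m["fs"]
            ident = dict(subject=m["subject"], trial=m["trial"],
                         condition=m["condition"])
            trials.append(SyntheticTrial(
                target_env=EnvelopeSeries(npz[f"{key}__target"], fs=fs,
                                          role="target"),
                masker_env=EnvelopeSeries(npz[f"{key}__masker"], fs=fs,
                                          role="masker"),
                clean_eeg=EEGRecording(
                    npz[f"{key}__clean"], fs=fs,
                    channel_names=tuple(m["channel_names"]), **ident),
                observed_eeg=EEGRecording(
                    npz[f"{key}__observed"], fs=fs,
                    channel_names=tuple(m["channel_names"]), **ident),
                **ident,
            ))
    return trials


def write_envelope(env: EnvelopeSeries, path: str | Path) -> Path:
    """Single-column text series with a ``# fs=..., role=...`` header."""
    path = Path(path)
    header = f"fs={env.fs}, role={env.role}"
    np.savetxt(path, env.data, header=header)
    return path


def read_envelope(path: str | Path) -> EnvelopeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path} has no envelope header line")
    fields = dict(part.strip().split("=", 1)
                  for part in first.lstrip("# ").split(","))
    data = np.loadtxt(path)
    return EnvelopeSeries(data, fs=float(fields["fs"]),
                          role=fields.get("role", "target").strip())


def write_trf_table(trf: TRFSet, path: str | Path) -> Path:
    """TRF as a tidy table (channel, predictor, lag_ms, coefficient) with
    a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for ci, ch in enumerate(trf.channel_names):
        for pi, role in enumerate(trf.predictor_roles):
            for ki, lag in enumerate(trf.lag_grid.lags_ms):
                rows.append((ch, role, lag, trf.coefficients[ci, pi, ki]))
    pd.DataFrame(rows, columns=["channel", "predictor", "lag_ms",
                                "coefficient"]).to_csv(path, index=False)
    meta = {
        "fs": trf.fs,
        "subject": trf.subject,
        "trial": trf.trial,
        "condition": trf.condition,
        "channel_names": list(trf.channel_names),
        "predictor_roles": list(trf.predictor_roles),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_trf_table(path: str | Path) -> TRFSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    channels = meta["channel_names"]
    roles = meta["predictor_roles"]
    lags = np.sort(df["lag_ms"].unique())
    coef = np.zeros((len(channels), len(roles), lags.size))
    ch_i = {c: i for i, c in enumerate(channels)}
    p_i = {r: i for i, r in enumerate(roles)}
    lag_i = {l: i for i, l in enumerate(lags)}
    for row in df.itertuples(index=False):
        coef[ch_i[row.channel], p_i[row.predictor],
             lag_i[row.lag_ms]] = row.coefficient
    return TRFSet(coefficients=coef, lag_grid=LagGrid(lags),
                  predictor_roles=tuple(roles), fs=meta["fs"],
                  channel_names=tuple(channels), subject=meta["subject"],
                  trial=meta["trial"], condition=meta["condition"])
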