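"""CSV/YAML/JSON dialects for recordings, events, features and configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events_types import GaitEvent, GaitEventList
from .simulate import GaitRecording, SimConfig

__all__ = [
    "write_recording", "read_recording", "write_events", "read_events",
    "write_features", "read_features", "config_to_yaml", "config_from_yaml",
    "derive_seed",
]

EMG_PREFIX = "emg_"


def derive_seed(master: int, stage: int) -> int:
    """Counter-based per-stage seed fan-out from one master seed (< 2^31)."""
    return int(np.random.SeedSequence([int(master), int(stage)]).generate_state(1)[0] % (2**31))


def write_recording(recording: GaitRecording, path) -> None:
    """recording.csv: time_s, emg_<muscle>..., grf_ipsi, grf_contra."""
    n = recording.n_samples
    cols = {"time_s": np.arange(n) / recording.fs}
    for i, name in enumerate(recording.muscle_names):
        cols[f"{EMG_PREFIX}{name}"] = recording.emg[i]
    cols["grf_ipsi"] = recording.grf_ipsi
    cols["grf_contra"] = recording.grf_contra
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_recording(path, expected_muscles: tuple[str, ...] = ("TA", "SOL", "GL", "RF")):
    """Read a recording.csv; returns (emg, grf_ipsi, grf_contra, fs, muscle_names)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty recording file")
    for col in ("time_s", "grf_ipsi", "grf_contra"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    emg_cols = [c for c in df.columns if c.startswith(EMG_PREFIX)]
    names = tuple(c[len(EMG_PREFIX):] for c in emg_cols)
    if expected_muscles is not None and names != tuple(expected_muscles):
        raise ValueError(
            f"{path}: EMG columns {names} do not match expected {tuple(expected_muscles)}"
        )
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: non-uniform sampling (mixed rates?)")
    fs = 1.0 / dt[0] if len(dt) else 0.0
    emg = df[emg_cols].to_numpy().T
    return emg, df["grf_ipsi"].to_numpy(), df["grf_contra"].to_numpy(), fs, names


def write_events(events: GaitEventList, path) -> None:
    pd.DataFrame(
        {"type": [e.type for e in events], "time_s": [e.time_s for e in events]}
    ).to_csv(path, index=False, float_format="%.17g")


def read_events(path) -> GaitEventList:
    df = pd.read_csv(path, float_precision="round_trip")
    return GaitEventList([GaitEvent(r.type, float(r.time_s)) for r in df.itertuples()])


def write_features(values: np.ndarray, names: list[str], path, meta: dict | None = None) -> None:
    """Features CSV (one row per window) with a JSON sidecar of parameters."""
    pd.DataFrame(values, columns=names).to_csv(path, index=False, float_format="%.17g")
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))


def read_features(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df.to_numpy(), list(df.columns)


def _cfg_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["true_weights"] = np.asarray(d["true_weights"]).tolist()
    d["muscle_names"] = list(d["muscle_names"])
    d["burst_centers"] = [list(c) for c in d["burst_centers"]]
    d["burst_widths"] = [list(w) for w in d["burst_widths"]]
    return d


def config_to_yaml(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_cfg_dict(cfg), sort_keys=False))


def config_from_yaml(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["muscle_names"] = tuple(d.get("muscle_names", ("TA", "SOL", "GL", "RF")))
    d["true_weights"] = np.asarray(d["true_weights"])
    d["burst_centers"] = tuple(tuple(c) for c in d["burst_centers"])
    d["burst_widths"] = tuple(tuple(w) for w in d["burst_widths"])
    return SimConfig(**d)


def write_windows_manifest(windows, path) -> None:
    """Manifest CSV for a LabeledWindowSet: start/end sample and label."""
    pd.DataFrame({
        "start_index": windows.starts,
        "end_index": windows.ends,
        "label": [windows.classes[i] for i in windows.labels],
    }).to_csv(path, index=False)
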