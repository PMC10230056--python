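"""End-to-end orchestration: simulate -> preprocess -> label/segment ->
features -> (balance) -> cross-validate -> post-process -> event matching.

The reference phase labels come from the GRF-detected events, exactly as a
force-plate protocol would produce them; the simulator's stored truth is
only used to validate the detector itself.  Time-domain, wavelet and raw
feature banks are computed on the band-pass-filtered EMG windows; the
muscle-synergy bank on the linear-envelope windows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .classify import ClassifierSpec, CVResult, crossvalidate
from .events_eval import PostprocessSpec, extract_transitions, match_events, postprocess
from .events_types import GaitEventList
from .features import RawSamples, TimeDomainFeatures, WaveletCoefficients, WaveletFeatures
from .labeling import LabeledWindowSet, as_scheme, phase_labels, segment_windows
from .preprocess import (BAND_PASS_DEFAULT, LOW_PASS_DEFAULT, combine_bilateral_events,
                         detect_events_from_grf, emg_envelope)
from .simulate import GaitRecording, SimConfig, simulate_recording
from .synergy import MuscleSynergyFeatures

log = logging.getLogger("synergait")

FEATURE_KINDS = ("TD", "WC", "WF", "RE", "MS")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    scheme: str = "3class"
    window_len_ms: float = 200.0
    interval_samples: int = 5
    obs_samples: int = 5
    feature_kinds: tuple = ("MS", "TD")
    wavelet: str = "sym7"
    wavelet_level: int = 5
    ar_order: int = 4
    eps: float = 0.0
    synergy_k: int = 1
    n_restarts: int = 20
    nnmf_max_iter: int = 500
    nnmf_tol: float = 1e-6
    balance: bool = True
    k_neighbors: int = 5
    classifier: str = "SVM"
    folds: int = 10
    val_frac: float = 0.1
    search_budget: int = 20
    grf_threshold_N: float = 20.0
    tolerance_ms: float = 2.5
    relaxed_tolerance_ms: float = 50.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        as_scheme(self.scheme)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.val_frac < 1):
            raise ValueError("val_frac must be in (0, 1)")
        unknown = set(self.feature_kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds {unknown}")
        if self.window_len_ms <= 0 or self.interval_samples < 1 or self.obs_samples < 1:
            raise ValueError("invalid segmentation parameters")

    @property
    def window_len_samples(self) -> int:
        return int(round(self.window_len_ms / 1000.0 * self.sim.fs))


@dataclass
class SubjectData:
    """One recording carried through preprocessing and segmentation."""

    recording: GaitRecording
    envelope: np.ndarray
    ref_events: GaitEventList          # GRF-detected, bilateral, ipsi frame
    raw_windows: LabeledWindowSet      # band-passed EMG (TD/WC/WF/RE input)
    env_windows: LabeledWindowSet      # linear envelope (MS input)


def prepare_subject(recording: GaitRecording, cfg: PipelineConfig) -> SubjectData:
    scheme = as_scheme(cfg.scheme)
    band = BAND_PASS_DEFAULT.apply(recording.emg, recording.fs)
    envelope = emg_envelope(recording.emg, recording.fs)
    ipsi = detect_events_from_grf(recording.grf_ipsi, recording.fs, cfg.grf_threshold_N)
    contra = detect_events_from_grf(recording.grf_contra, recording.fs, cfg.grf_threshold_N)
    ref = combine_bilateral_events(ipsi, contra)
    labels = phase_labels(ref, recording.n_samples, recording.fs, scheme)
    kw = dict(
        labels=labels,
        window_len=cfg.window_len_samples,
        interval=cfg.interval_samples,
        obs_len=cfg.obs_samples,
        classes=scheme.classes,
        fs=recording.fs,
    )
    return SubjectData(
        recording=recording,
        envelope=envelope,
        ref_events=ref,
        raw_windows=segment_windows(band, **kw),
        env_windows=segment_windows(envelope, **kw),
    )


def feature_names(kind: str, dim: int, muscles: tuple[str, ...]) -> list[str]:
    per = dim // len(muscles)
    return [f"{kind}_{m}_{i}" for m in muscles for i in range(per)]


def extract_features(sub: SubjectData, kind: str, cfg: PipelineConfig) -> np.ndarray:
    if kind == "TD":
        return TimeDomainFeatures(ar_order=cfg.ar_order, eps=cfg.eps).transform(sub.raw_windows.data)
    if kind == "WC":
        return WaveletCoefficients(cfg.wavelet, cfg.wavelet_level).transform(sub.raw_windows.data)
    if kind == "WF":
        return WaveletFeatures(cfg.wavelet, cfg.wavelet_level).transform(sub.raw_windows.data)
    if kind == "RE":
        return RawSamples().transform(sub.raw_windows.data)
    if kind == "MS":
        return MuscleSynergyFeatures(
            k=cfg.synergy_k, n_restarts=cfg.n_restarts, max_iter=cfg.nnmf_max_iter,
            tol=cfg.nnmf_tol, random_state=sio.derive_seed(cfg.master_seed, 5),
        ).transform(sub.env_windows.data)
    raise ValueError(f"unknown feature kind {kind!r}")


def evaluate_features(sub: SubjectData, X: np.ndarray, cfg: PipelineConfig,
                      kind: str) -> dict:
    """Cross-validate one feature bank and score the implied gait events."""
    scheme = as_scheme(cfg.scheme)
    ws = sub.env_windows
    spec = ClassifierSpec(kind=cfg.classifier, search_budget=cfg.search_budget,
                          seed=sio.derive_seed(cfg.master_seed, 11))
    cv = crossvalidate(X, ws.labels, spec, folds=cfg.folds, val_frac=cfg.val_frac,
                       balance=cfg.balance, k_neighbors=cfg.k_neighbors,
                       scheme=scheme.name, feature_kind=kind)
    pp_spec = PostprocessSpec(label_rate_hz=ws.label_rate_hz)
    cleaned = postprocess(cv.predictions, scheme, pp_spec)
    t0 = ws.end_times_s()[0]
    pred_events, anomalies = extract_transitions(cleaned, scheme, ws.label_rate_hz, t0)
    etypes = ("IC", "OFC", "OIC") if scheme.name == "3class" else ("IC", "FC")
    t_end = ws.end_times_s()[-1]
    truth = GaitEventList([
        e for e in sub.ref_events if e.type in etypes and t0 <= e.time_s <= t_end
    ])
    reports = {
        f"tolerance_{tol:g}ms": match_events(pred_events, truth, tolerance_ms=tol,
                                             event_types=etypes).to_dict()
        for tol in (cfg.tolerance_ms, cfg.relaxed_tolerance_ms)
    }
    return {
        "feature_kind": kind,
        "scheme": scheme.name,
        "fold_accuracies": cv.fold_accuracies.tolist(),
        "mean_accuracy": cv.mean_accuracy,
        "sd_accuracy": cv.sd_accuracy,
        "n_windows": int(ws.n_windows),
        "n_transition_anomalies": len(anomalies),
        "event_reports": reports,
        "_cv": cv,
        "_pred_events": pred_events,
        "_truth_events": truth,
    }


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and write artifacts; returns the metrics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO, force=True)
    log.info("config: %s", dataclasses.asdict(cfg))

    recording = simulate_recording(cfg.sim)
    sio.write_recording(recording, out / "recording.csv")
    sio.write_events(recording.truth_events, out / "events.csv")
    sio.config_to_yaml(cfg.sim, out / "sim_config.yaml")

    sub = prepare_subject(recording, cfg)
    metrics = {
        "scheme": cfg.scheme,
        "master_seed": cfg.master_seed,
        "n_windows": int(sub.env_windows.n_windows),
        "conventions": {
            "wavelet_mode": "symmetric", "tie_break": "latest-occurring maximal class",
            "eps": cfg.eps, "window_len_samples": cfg.window_len_samples,
        },
        "features": {},
    }
    muscles = recording.muscle_names
    for kind in cfg.feature_kinds:
        log.info("feature bank %s", kind)
        X = extract_features(sub, kind, cfg)
        sio.write_features(X, feature_names(kind, X.shape[1], muscles),
                           out / f"features_{kind}.csv",
                           meta={"kind": kind, "window_len": cfg.window_len_samples})
        res = evaluate_features(sub, X, cfg, kind)
        metrics["features"][kind] = {
            k: v for k, v in res.items() if not k.startswith("_")
        }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    log.info("done")
    return metrics
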