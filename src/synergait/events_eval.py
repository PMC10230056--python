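"""Gait-event identification from predicted phase-label series.

The predicted label stream (window rate, 400 Hz when windows slide by
5 samples of a 2000 Hz signal) is first cleaned by a run-length rule:
any phase run shorter than a physiologically plausible minimum duration
is removed and merged into the preceding retained phase.  The minimums are
5% of the reference mean gait cycle for weight acceptance (54.69 ms) and
20% (218.75 ms) for all other phases.  Phase transitions of the cleaned
stream are then typed as gait events (WA->SS is OFC, SS->LA is OIC,
LA->WA is IC; ST->SW is FC, SW->ST is IC) and matched one-to-one against
ground truth to score MAE, precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events_types import GaitEvent, GaitEventList
from .labeling import PhaseScheme, as_scheme

__all__ = ["PostprocessSpec", "EventMatchReport", "postprocess",
           "extract_transitions", "match_events"]

# minimum plausible run durations, as fractions of the mean gait cycle:
# 5% for weight acceptance, 20% for everything else (1.09375 s reference
# cycle makes these 54.69 ms and 218.75 ms)
DEFAULT_MIN_DURATION_MS = {
    "WA": 54.69, "SS": 218.75, "LA": 218.75, "ST": 218.75, "SW": 218.75,
}

# phase transition -> event type
TRANSITION_EVENTS = {
    ("WA", "SS"): "OFC", ("SS", "LA"): "OIC", ("LA", "WA"): "IC",
    ("ST", "SW"): "FC", ("SW", "ST"): "IC",
}
# canonical entry event of each phase (used for illegal transitions)
ENTRY_EVENT = {"WA": "IC", "SS": "OFC", "LA": "OIC", "ST": "IC", "SW": "FC"}


@dataclass(frozen=True)
class PostprocessSpec:
    min_duration_ms: dict = field(default_factory=lambda: dict(DEFAULT_MIN_DURATION_MS))
    label_rate_hz: float = 400.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.min_duration_ms.values()):
            raise ValueError("all minimum durations must be positive")
        if self.label_rate_hz <= 0:
            raise ValueError("label_rate_hz must be positive")

    def min_samples(self, label: str) -> float:
        """Run length (in label samples) below which a run is removed."""
        return self.min_duration_ms[label] * self.label_rate_hz / 1000.0


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) runs of a label series."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def postprocess(labels, scheme, spec: PostprocessSpec | None = None) -> np.ndarray:
    """Remove implausibly short runs, merging them into the previous phase.

    Runs whose duration is strictly below their class minimum are deleted
    and their samples take the preceding retained run's label (the first
    run, having no predecessor, merges forward); this repeats until no
    sub-threshold run remains, so the operation is idempotent.
    """
    scheme = as_scheme(scheme)
    spec = spec or PostprocessSpec()
    out = np.asarray(labels).copy()
    if out.size == 0:
        return out
    names = scheme.classes
    while True:
        runs = _runs(out)
        if len(runs) <= 1:
            break
        removed = False
        for i, (s, n) in enumerate(runs):
            lbl = names[int(out[s])]
            if n < spec.min_samples(lbl):
                if i > 0:
                    out[s : s + n] = out[runs[i - 1][0]]
                else:
                    out[s : s + n] = out[runs[i + 1][0]]
                removed = True
                break
        if not removed:
            break
    return out


def extract_transitions(labels, scheme, label_rate_hz: float = 400.0,
                        t0_s: float = 0.0) -> tuple[GaitEventList, list]:
    """Type the phase transitions of a cleaned label series as gait events.

    The event time is the time of the first sample of the new phase
    (``t0_s`` locates sample 0 on the recording clock).  Illegal
    transitions (e.g. WA -> LA) are typed by the destination phase's
    canonical entry event and reported in the anomaly list.
    """
    scheme = as_scheme(scheme)
    labels = np.asarray(labels)
    names = scheme.classes
    events: list[GaitEvent] = []
    anomalies: list[tuple[int, str, str]] = []
    runs = _runs(labels)
    for prev, cur in zip(runs, runs[1:]):
        a, b = names[int(labels[prev[0]])], names[int(labels[cur[0]])]
        t = t0_s + cur[0] / label_rate_hz
        etype = TRANSITION_EVENTS.get((a, b))
        if etype is None:
            etype = ENTRY_EVENT[b]
            anomalies.append((cur[0], a, b))
        events.append(GaitEvent(etype, t))
    return GaitEventList(events), anomalies


@dataclass
class EventMatchReport:
    """Per-event-type matching scores between predicted and truth events."""

    per_type: dict = field(default_factory=dict)
    tolerance_ms: float = 2.5
    max_match_ms: float = 546.9
    empty_truth_types: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            etype: {k: (float(v) if v == v else None) for k, v in d.items()}
            for etype, d in self.per_type.items()
        } | {"tolerance_ms": self.tolerance_ms, "max_match_ms": self.max_match_ms}


def _greedy_match(truth: np.ndarray, pred: np.ndarray, max_match_s: float):
    """Greedy nearest-time one-to-one matching; returns index pairs."""
    pairs = []
    for i, t in enumerate(truth):
        for j, p in enumerate(pred):
            d = abs(p - t)
            if d <= max_match_s:
                pairs.append((d, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = []
    for d, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        matched.append((i, j, d))
    return matched


def match_events(
    pred: GaitEventList,
    truth: GaitEventList,
    tolerance_ms: float = 2.5,
    max_match_ms: float = 546.9,
    event_types: tuple | None = None,
) -> EventMatchReport:
    """Score predicted against truth events, per event type.

    Within each type, truth and predicted events are matched greedily
    nearest-first, one-to-one, within ``max_match_ms``.  A matched pair
    with |dt| <= ``tolerance_ms`` is a TP; a matched pair outside the
    tolerance counts as both a FP and a FN; unmatched predictions are FPs
    and unmatched truths FNs.  MAE is averaged over all matched pairs,
    irrespective of the TP tolerance, so the two accounting conventions
    are reported side by side.
    """
    report = EventMatchReport(tolerance_ms=tolerance_ms, max_match_ms=max_match_ms)
    if event_types is None:
        event_types = tuple(sorted({e.type for e in truth} | {e.type for e in pred}))
    tol_s = tolerance_ms / 1000.0
    for etype in event_types:
        t_times = truth.times(etype)
        p_times = pred.times(etype)
        matched = _greedy_match(t_times, p_times, max_match_ms / 1000.0)
        tp = sum(1 for _, _, d in matched if d <= tol_s + 1e-12)
        off_tol = len(matched) - tp
        fp = (len(p_times) - len(matched)) + off_tol
        fn = (len(t_times) - len(matched)) + off_tol
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
        sum_abs_dt_ms = float(sum(d for _, _, d in matched) * 1000.0)
        mae_ms = sum_abs_dt_ms / len(matched) if matched else float("nan")
        if len(t_times) == 0:
            report.empty_truth_types.append(etype)
        report.per_type[etype] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
            "mae_ms": mae_ms, "n_truth": len(t_times), "n_pred": len(p_times),
            "n_matched": len(matched), "sum_abs_dt_ms": sum_abs_dt_ms,
        }
    return report
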