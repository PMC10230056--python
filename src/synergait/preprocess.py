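"""EMG envelope extraction and GRF conditioning.

The envelope pipeline is the classic surface-EMG recipe: zero-lag (forward-
backward) Butterworth band-pass, full-wave rectification, then a zero-lag
4th-order Butterworth low-pass at 5 Hz.  Gait events are read off the
vertical ground reaction force by threshold crossing with a debounce, the
standard force-plate definition of initial contact (heel strike) and final
contact (toe off).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .events_types import GaitEvent, GaitEventList

__all__ = [
    "FilterSpec",
    "bandlimit",
    "emg_envelope",
    "detect_events_from_grf",
    "combine_bilateral_events",
    "downsample_series",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter stage.

    Parameters
    ----------
    kind : {"bandpass", "lowpass"}
    cutoffs : tuple of float
        Cutoff frequencies in Hz; one value for lowpass, two for bandpass.
    order : int
        Filter order (of the underlying one-pass design).
    zero_lag : bool
        Apply forward-backward (``sosfiltfilt``) so the stage has zero
        phase delay.
    """

    kind: str = "bandpass"
    cutoffs: tuple[float, ...] = (20.0, 350.0)
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(self.cutoffs) != n_expected:
            raise ValueError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {self.cutoffs}"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive")

    def sos(self, fs: float):
        nyq = fs / 2.0
        if any(c >= nyq for c in self.cutoffs):
            raise ValueError(
                f"cutoffs {self.cutoffs} not strictly inside (0, {nyq}) at fs={fs}"
            )
        wn = self.cutoffs if self.kind == "bandpass" else self.cutoffs[0]
        return signal.butter(self.order, wn, btype=self.kind, fs=fs, output="sos")

    def apply(self, x: np.ndarray, fs: float, axis: int = -1) -> np.ndarray:
        sos = self.sos(fs)
        if self.zero_lag:
            return signal.sosfiltfilt(sos, x, axis=axis)
        return signal.sosfilt(sos, x, axis=axis)


BAND_PASS_DEFAULT = FilterSpec("bandpass", (20.0, 350.0), order=4, zero_lag=True)
LOW_PASS_DEFAULT = FilterSpec("lowpass", (5.0,), order=4, zero_lag=True)


def bandlimit(x: np.ndarray, fs: float, spec: FilterSpec = BAND_PASS_DEFAULT) -> np.ndarray:
    """Band-limit a signal with the same zero-lag primitive used everywhere."""
    return spec.apply(np.asarray(x, dtype=float), fs)


def emg_envelope(
    raw_emg: np.ndarray,
    fs: float,
    band: FilterSpec = BAND_PASS_DEFAULT,
    low: FilterSpec = LOW_PASS_DEFAULT,
) -> np.ndarray:
    """Linear-envelope extraction: band-pass, rectify, low-pass, clip at 0.

    Parameters
    ----------
    raw_emg : ndarray, shape (muscles, samples) or (samples,)
        Raw EMG, arbitrary units.
    fs : float
        Sampling rate in Hz; must exceed twice the band-pass upper cutoff.

    Returns
    -------
    ndarray of the same shape, nonnegative.
    """
    x = np.asarray(raw_emg, dtype=float)
    if np.isnan(x).all(axis=-1).any():
        raise ValueError("all-NaN channel in EMG input")
    filtered = band.apply(x, fs)
    rectified = np.abs(filtered)
    env = low.apply(rectified, fs)
    return np.clip(env, 0.0, None)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean series as (start, length, value)."""
    if mask.size == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [mask.size]))
    return [(int(s), int(e - s), bool(mask[s])) for s, e in zip(starts, ends)]


def detect_events_from_grf(
    grf: np.ndarray,
    fs: float,
    threshold: float = 20.0,
    debounce_s: float = 0.05,
) -> GaitEventList:
    """Detect IC/FC events from vertical GRF by debounced threshold crossing.

    A crossing only counts if the new contact state (above/below
    ``threshold``) persists at least ``debounce_s`` seconds; shorter blips
    are merged into the surrounding state before crossings are read off.
    """
    grf = np.asarray(grf, dtype=float)
    if grf.ndim != 1:
        raise ValueError("grf must be 1-D")
    if np.any(grf < 0):
        raise ValueError("grf must be nonnegative")
    above = grf > threshold
    min_len = max(1, int(round(debounce_s * fs)))
    runs = _runs(above)
    # drop sub-debounce runs (except a leading/trailing partial) by merging
    # them into the preceding state, repeating until stable
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (s, n, v) in enumerate(runs):
            if n < min_len and 0 < i < len(runs) - 1:
                runs[i] = (s, n, runs[i - 1][2])
                # merge equal-valued neighbours
                merged: list[tuple[int, int, bool]] = []
                for r in runs:
                    if merged and merged[-1][2] == r[2]:
                        ps, pn, pv = merged[-1]
                        merged[-1] = (ps, pn + r[1], pv)
                    else:
                        merged.append(r)
                runs = merged
                changed = True
                break
    events: list[GaitEvent] = []
    for prev, cur in zip(runs, runs[1:]):
        t = cur[0] / fs
        if cur[2] and not prev[2]:
            events.append(GaitEvent("IC", t))
        elif prev[2] and not cur[2]:
            events.append(GaitEvent("FC", t))
    return GaitEventList(events)


def combine_bilateral_events(ipsi: GaitEventList, contra: GaitEventList) -> GaitEventList:
    """Merge contralateral IC/FC into the ipsilateral frame as OIC/OFC.

    For a normal duty factor the within-cycle ordering is
    IC < OFC < OIC < next IC; a schedule in which the two stances never
    overlap is flagged with a warning but still merged.
    """
    relabel = {"IC": "OIC", "FC": "OFC"}
    merged = list(ipsi.events) + [
        GaitEvent(relabel[e.type], e.time_s) for e in contra.events if e.type in relabel
    ]
    merged.sort(key=lambda e: (e.time_s, e.type))
    out = GaitEventList(merged)
    ic = out.times("IC")
    ofc = out.times("OFC")
    if len(ic) >= 2 and len(ofc) > 0:
        # double support exists iff some OFC falls after an IC within stance
        cycles = list(zip(ic[:-1], ic[1:]))
        ok = any(any(a < t < b for a, b in cycles) for t in ofc)
        if not ok:
            warnings.warn("no double-support overlap found in merged schedule")
    return out


def downsample_series(x: np.ndarray, factor: int) -> np.ndarray:
    """Stride-decimate ``x`` by ``factor`` (keeping x[0], x[factor], ...).

    Used only to align label/GRF sampling grids (e.g. 2000 Hz -> 400 Hz);
    no anti-alias filtering, by design.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    return np.asarray(x)[::factor]
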