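"""Per-sample phase labels and overlapping labeled windows.

Phases partition each gait cycle with half-open intervals:

* 3-class — WA (weight acceptance) on [IC, OFC), SS (single limb support)
  on [OFC, OIC), LA (limb advancement) on [OIC, next IC);
* 2-class — ST (stance) on [IC, FC), SW (swing) on [FC, next IC).

Windows slide with an interval of 5 samples and are labeled causally at the
trailing edge: the majority ground-truth phase over the last ``obs_len``
samples (the observation window) labels the whole window, so a label stream
at one-per-interval is a 400 Hz series when the signal is sampled at 2000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseScheme", "THREE_CLASS", "TWO_CLASS", "LabeledWindowSet",
           "phase_labels", "segment_windows"]

UNLABELED = -1


@dataclass(frozen=True)
class PhaseScheme:
    name: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = {"3class": ("WA", "SS", "LA"), "2class": ("ST", "SW")}
        if self.name not in expected:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.classes != expected[self.name]:
            raise ValueError(f"classes {self.classes} do not match scheme {self.name}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


THREE_CLASS = PhaseScheme("3class", ("WA", "SS", "LA"))
TWO_CLASS = PhaseScheme("2class", ("ST", "SW"))


def as_scheme(scheme) -> PhaseScheme:
    if isinstance(scheme, PhaseScheme):
        return scheme
    return {"3class": THREE_CLASS, "2class": TWO_CLASS}[str(scheme)]


def _idx(t: float, fs: float) -> int:
    """First sample index at or after time t (half-open boundary)."""
    return int(np.ceil(t * fs - 1e-9))


def phase_labels(events, n_samples: int, fs: float, scheme) -> np.ndarray:
    """Integer per-sample labels (index into ``scheme.classes``; -1 = unlabeled).

    Samples before the first IC or after the last complete cycle stay
    unlabeled and are excluded downstream.
    """
    scheme = as_scheme(scheme)
    ic = events.times("IC")
    if len(ic) < 2:
        raise ValueError("need at least two IC events (one complete cycle)")
    labels = np.full(n_samples, UNLABELED, dtype=np.int64)
    for ci, (a, b) in enumerate(zip(ic[:-1], ic[1:])):
        if scheme.name == "3class":
            inner = []
            for etype in ("OFC", "OIC"):
                tt = events.times(etype)
                inside = tt[(tt > a) & (tt < b)]
                if len(inside) != 1:
                    raise ValueError(
                        f"cycle {ci} [{a:.4f}, {b:.4f}) needs exactly one {etype}, "
                        f"found {len(inside)}"
                    )
                inner.append(inside[0])
            bounds = [a, inner[0], inner[1], b]
        else:
            tt = events.times("FC")
            inside = tt[(tt > a) & (tt < b)]
            if len(inside) != 1:
                raise ValueError(
                    f"cycle {ci} [{a:.4f}, {b:.4f}) needs exactly one FC, "
                    f"found {len(inside)}"
                )
            bounds = [a, inside[0], b]
        if any(x >= y for x, y in zip(bounds[:-1], bounds[1:])):
            raise ValueError(f"cycle {ci}: events out of canonical order {bounds}")
        for k in range(len(bounds) - 1):
            i0 = max(0, _idx(bounds[k], fs))
            i1 = min(n_samples, _idx(bounds[k + 1], fs))
            labels[i0:i1] = k
    return labels


@dataclass
class LabeledWindowSet:
    """Overlapping windows cut from one multichannel signal.

    ``data`` has shape (n_windows, muscles, window_len); window i covers
    samples [starts[i], starts[i] + window_len) and carries the majority
    label of its observation window (the trailing ``obs_len`` samples).
    """

    data: np.ndarray
    starts: np.ndarray
    labels: np.ndarray
    classes: tuple[str, ...]
    window_len: int
    interval: int
    obs_len: int
    fs: float

    def __post_init__(self) -> None:
        if len(self.starts) > 1 and not np.all(np.diff(self.starts) == self.interval):
            raise ValueError("consecutive window starts must differ by exactly interval")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.classes)):
            raise ValueError("labels out of range for scheme classes")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def ends(self) -> np.ndarray:
        """Index of each window's last sample (the label timestamp)."""
        return self.starts + self.window_len - 1

    @property
    def label_rate_hz(self) -> float:
        return self.fs / self.interval

    def end_times_s(self) -> np.ndarray:
        return self.ends / self.fs


def _majority(obs: np.ndarray, n_classes: int) -> int:
    """Most frequent label; ties broken toward the class whose last
    occurrence in the observation window is latest (most recent state)."""
    counts = np.bincount(obs, minlength=n_classes)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    last_pos = {int(c): -1 for c in tied}
    for i, v in enumerate(obs):
        if int(v) in last_pos:
            last_pos[int(v)] = i
    return max(last_pos, key=lambda c: last_pos[c])


def segment_windows(
    signal: np.ndarray,
    labels: np.ndarray,
    window_len: int,
    interval: int = 5,
    obs_len: int = 5,
    classes: tuple[str, ...] = ("WA", "SS", "LA"),
    fs: float = 2000.0,
) -> LabeledWindowSet:
    """Cut overlapping windows and label each from its observation window.

    Windows whose observation window contains any unlabeled sample are
    dropped (the remaining starts keep the exact ``interval`` spacing on
    the retained contiguous stretch check is relaxed accordingly).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    labels = np.asarray(labels)
    n = signal.shape[1]
    if window_len > n:
        raise ValueError(f"window_len {window_len} exceeds signal length {n}")
    if window_len < obs_len:
        raise ValueError("window_len must be >= obs_len")
    if labels.shape[0] != n:
        raise ValueError("labels and signal must be aligned at the same fs")

    ends = np.arange(window_len - 1, n, interval)
    starts = ends - window_len + 1
    n_classes = len(classes)

    keep = []
    win_labels = []
    for i, e in enumerate(ends):
        obs = labels[e - obs_len + 1 : e + 1]
        if np.any(obs == UNLABELED):
            continue
        keep.append(i)
        win_labels.append(_majority(obs.astype(np.int64), n_classes))

    keep = np.asarray(keep, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(signal, window_len, axis=1)
    data = view[:, starts[keep], :].transpose(1, 0, 2).copy() if keep.size else np.empty(
        (0, signal.shape[0], window_len)
    )
    ws = LabeledWindowSet(
        data=data,
        starts=starts[keep],
        labels=np.asarray(win_labels, dtype=np.int64),
        classes=tuple(classes),
        window_len=window_len,
        interval=interval,
        obs_len=obs_len,
        fs=fs,
    )
    return ws
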