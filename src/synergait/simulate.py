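"""Synthetic treadmill-walking EMG/GRF generator with known ground truth.

The generator emulates a ~1-min walk recorded at 2000 Hz from four lower-limb
muscles (TA, SOL, GL, RF) plus bilateral vertical ground reaction force:

* quasi-periodic gait cycles with truncated-normal durations and a fixed
  stance duty factor (default 60%);
* a known muscle-synergy structure: per-sample activation envelope
  ``true_weights @ H`` where each row of ``H`` is a cycle-phase-locked burst
  train (smoothed plateaus with onset transients by default, or Gaussian
  bursts), with per-cycle lognormal amplitude jitter emulating step-to-step
  variability;
* surface EMG modelled as the envelope amplitude-modulating band-limited
  (20-350 Hz) unit-variance noise, plus a small white noise floor;
* an M-shaped (two-peak) stance-only vertical GRF whose support defines the
  ground-truth contact events; the contralateral side is the ipsilateral
  schedule shifted by half a cycle.

Every downstream stage can therefore be checked against stored truth:
envelope, synergy weights, per-sample phase, and IC/FC/OIC/OFC event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events_types import GaitEvent, GaitEventList
from .preprocess import BAND_PASS_DEFAULT, FilterSpec, bandlimit

__all__ = ["SimConfig", "GaitRecording", "simulate_recording", "truth_phase_series"]

MUSCLES_DEFAULT = ("TA", "SOL", "GL", "RF")

# Default synergy structure: four patterns mirroring the textbook timing of
# lower-limb EMG over the gait cycle, with activation switches at the gait
# events themselves (as in real walking, where muscle onsets are locked to
# the biomechanical events):
#   loading response (quadriceps-led: RF with TA co-activation) during
#   weight acceptance [0, 10.5%),
#   push-off (SOL + GL plantarflexors) through single support [10.5%, 50%),
#   pre-swing / limb-advancement initiation (RF hip flexion with GL
#   carryover) [50%, 60%), and
#   swing dorsiflexion (TA foot clearance) [60%, 97%).
# The four signatures are pairwise distinct in muscle space so that every
# phase boundary is a detectable change of muscle ratios.
TRUE_WEIGHTS_DEFAULT = np.array(
    [
        # loading push-off pre-swing swing
        [0.45, 0.05, 0.05, 1.00],  # TA
        [0.05, 1.00, 0.20, 0.05],  # SOL
        [0.05, 0.85, 0.45, 0.05],  # GL
        [1.00, 0.05, 1.00, 0.10],  # RF
    ]
)
# plateau activations: (center, half-width) pairs in cycle-phase fractions;
# sustained plateaus carry a short doubled-amplitude plateau at their onset,
# emulating the recruitment (onset) transient of real muscle activations --
# the swing synergy's is the biphasic TA burst at toe-off
BURST_CENTERS_DEFAULT = ((0.0525,), (0.125, 0.3025), (0.52, 0.55), (0.62, 0.62, 0.785))
BURST_WIDTHS_DEFAULT = ((0.0525,), (0.025, 0.1975), (0.025, 0.05), (0.02, 0.02, 0.185))
# relative burst intensities: the loading response is the most prominent
# burst of the gait cycle; the pre-swing hip-flexor burst is short and strong
BURST_AMPLITUDES_DEFAULT = (2.2, 1.0, 1.5, 1.0)


@dataclass
class SimConfig:
    """Free parameters of the synthetic walking generator.

    The defaults reproduce the study conditions: 60 s at 2000 Hz, a mean
    gait cycle of 1.09375 s (so 5% and 20% of a cycle are the 54.69 ms and
    218.75 ms run-length thresholds used in post-processing), 60% stance
    duty factor and four muscles.
    """

    duration_s: float = 60.0
    fs: float = 2000.0
    mean_cycle_s: float = 1.09375
    cycle_sd_s: float = 0.03
    duty_factor: float = 0.60
    n_muscles: int = 4
    muscle_names: tuple[str, ...] = MUSCLES_DEFAULT
    true_weights: np.ndarray = field(default_factory=lambda: TRUE_WEIGHTS_DEFAULT.copy())
    burst_centers: tuple[tuple[float, ...], ...] = BURST_CENTERS_DEFAULT
    burst_widths: tuple[tuple[float, ...], ...] = BURST_WIDTHS_DEFAULT
    burst_shape: str = "plateau"   # "plateau" (smoothed boxcar) or "gauss"
    burst_edge: float = 0.01       # plateau edge transition width (phase fraction)
    burst_amplitudes: tuple[float, ...] | None = None  # per-synergy intensity
    amp_jitter_sd: float = 0.08
    emg_noise_floor: float = 0.02
    body_weight_N: float = 750.0
    grf_threshold_N: float = 20.0
    # edge ramp as a fraction of stance: GRF loads/unloads within ~1 ms of
    # the contact events (heel-strike impact / toe-off release), so the
    # contact threshold crossing marks the event to within a sample
    grf_ramp_frac: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if not (0.0 < self.duty_factor < 1.0):
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.mean_cycle_s <= 0 or self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("mean_cycle_s, duration_s and fs must be positive")
        if self.n_muscles <= 0:
            raise ValueError("n_muscles must be positive")
        if self.duration_s < self.mean_cycle_s:
            raise ValueError("duration_s shorter than one gait cycle")
        W = self.true_weights
        if W.ndim != 2 or W.shape[0] != self.n_muscles:
            raise ValueError(f"true_weights must be ({self.n_muscles}, K)")
        if np.any(W < 0):
            raise ValueError("true_weights must be nonnegative")
        if not np.allclose(W.max(axis=0), 1.0):
            raise ValueError("each true_weights column must have max 1")
        K = W.shape[1]
        if len(self.burst_centers) != K or len(self.burst_widths) != K:
            raise ValueError("burst_centers/burst_widths must have one entry per synergy")
        for widths in self.burst_widths:
            if any(w <= 0 for w in widths):
                raise ValueError("burst widths must be positive")
        if self.burst_shape not in ("plateau", "gauss"):
            raise ValueError("burst_shape must be 'plateau' or 'gauss'")
        if self.burst_edge <= 0:
            raise ValueError("burst_edge must be positive")
        if self.burst_amplitudes is None:
            self.burst_amplitudes = (
                BURST_AMPLITUDES_DEFAULT if K == len(BURST_AMPLITUDES_DEFAULT)
                else (1.0,) * K
            )
        if len(self.burst_amplitudes) != K or any(a <= 0 for a in self.burst_amplitudes):
            raise ValueError("burst_amplitudes must be K positive values")
        if self.cycle_sd_s < 0 or self.emg_noise_floor < 0:
            raise ValueError("cycle_sd_s and emg_noise_floor must be >= 0")

    @property
    def n_synergies(self) -> int:
        return self.true_weights.shape[1]


@dataclass
class GaitRecording:
    """One synthetic walking trial with its ground truth."""

    emg: np.ndarray              # (muscles, samples)
    grf_ipsi: np.ndarray         # (samples,), newtons
    grf_contra: np.ndarray       # (samples,), newtons
    fs: float
    muscle_names: tuple[str, ...]
    truth_events: GaitEventList
    truth_envelope: np.ndarray   # (muscles, samples), nonnegative
    config_used: SimConfig
    cycle_starts: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = self.emg.shape[1]
        if not (self.grf_ipsi.shape == self.grf_contra.shape == (n,)):
            raise ValueError("EMG and GRF arrays must share sample count")
        if np.any(self.grf_ipsi < 0) or np.any(self.grf_contra < 0):
            raise ValueError("GRF must be nonnegative")
        if np.any(self.truth_envelope < 0):
            raise ValueError("truth envelope must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _draw_cycles(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cycle durations (truncated normal at +-3 sd, always positive)."""
    durs: list[float] = []
    total = 0.0
    lo = max(1e-3, cfg.mean_cycle_s - 3 * cfg.cycle_sd_s)
    hi = cfg.mean_cycle_s + 3 * cfg.cycle_sd_s
    while total < cfg.duration_s + cfg.mean_cycle_s:
        if cfg.cycle_sd_s == 0:
            d = cfg.mean_cycle_s
        else:
            d = rng.normal(cfg.mean_cycle_s, cfg.cycle_sd_s)
            while not (lo <= d <= hi):
                d = rng.normal(cfg.mean_cycle_s, cfg.cycle_sd_s)
        durs.append(d)
        total += d
    return np.asarray(durs)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _grf_profile(n: int, fs: float, stance_intervals: list[tuple[float, float]],
                 cfg: SimConfig) -> np.ndarray:
    """Two-peak stance GRF: peaks ~1.1 body weight at 25%/75% of stance,
    a mid-stance valley at ~0.5 body weight, smooth rise/fall ramps at the
    stance edges, identically zero in swing."""
    grf = np.zeros(n)
    t = np.arange(n) / fs
    for start, end in stance_intervals:
        i0 = max(0, int(np.ceil(start * fs)))
        i1 = min(n, int(np.ceil(end * fs)))
        if i1 <= i0:
            continue
        s = (t[i0:i1] - start) / (end - start)
        m = cfg.body_weight_N * (0.8 + 0.3 * np.cos(4 * np.pi * (s - 0.25)))
        w = _smoothstep(s / cfg.grf_ramp_frac) * _smoothstep((1.0 - s) / cfg.grf_ramp_frac)
        grf[i0:i1] = m * w
    return grf


def simulate_recording(config: SimConfig | None = None, **overrides) -> GaitRecording:
    """Simulate one walking trial; same seed gives a bit-identical recording."""
    cfg = config if config is not None else SimConfig(**overrides)
    if overrides and config is not None:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))

    durs = _draw_cycles(cfg, rng)
    starts = np.concatenate(([0.0], np.cumsum(durs)))  # IC times, cycle i: [starts[i], starts[i+1])
    n_cycles = len(durs)

    # --- phase of every sample -------------------------------------------
    t = np.arange(n) / cfg.fs
    cyc_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
    phase = (t - starts[cyc_idx]) / durs[cyc_idx]

    # --- synergy activations H -------------------------------------------
    K = cfg.n_synergies
    H = np.zeros((K, n))
    if cfg.amp_jitter_sd > 0:
        gains = np.exp(rng.normal(0.0, cfg.amp_jitter_sd, size=(n_cycles, K)))
    else:
        gains = np.ones((n_cycles, K))
    for j in range(K):
        h = np.zeros(n)
        for c, w in zip(cfg.burst_centers[j], cfg.burst_widths[j]):
            d = phase - c
            d -= np.round(d)  # wrap to [-0.5, 0.5)
            if cfg.burst_shape == "plateau":
                # smoothed boxcar: 1 inside |d| < w - edge, smooth fall to 0 at |d| = w
                h += _smoothstep((w - np.abs(d)) / cfg.burst_edge)
            else:
                h += np.exp(-0.5 * (d / w) ** 2)
        H[j] = h * gains[cyc_idx, j] * cfg.burst_amplitudes[j]
    envelope = cfg.true_weights @ H

    # --- EMG: amplitude-modulated band-limited carrier + noise floor ------
    carrier = rng.standard_normal((cfg.n_muscles, n))
    carrier = bandlimit(carrier, cfg.fs, BAND_PASS_DEFAULT)
    carrier /= carrier.std(axis=1, keepdims=True)
    emg = envelope * carrier
    if cfg.emg_noise_floor > 0:
        emg = emg + cfg.emg_noise_floor * rng.standard_normal((cfg.n_muscles, n))

    # --- GRF + events -----------------------------------------------------
    ipsi_stance = [(starts[i], starts[i] + cfg.duty_factor * durs[i]) for i in range(n_cycles)]
    # contralateral schedule: ipsilateral shifted by half a cycle; a virtual
    # cycle before t=0 supplies the contra stance ending early in cycle 0
    contra_stance = [(-0.5 * durs[0], (-0.5 + cfg.duty_factor) * durs[0])]
    contra_stance += [
        (starts[i] + 0.5 * durs[i], starts[i] + (0.5 + cfg.duty_factor) * durs[i])
        for i in range(n_cycles)
    ]
    grf_ipsi = _grf_profile(n, cfg.fs, ipsi_stance, cfg)
    grf_contra = _grf_profile(n, cfg.fs, contra_stance, cfg)

    dur_total = n / cfg.fs
    events: list[GaitEvent] = []
    for (a, b) in ipsi_stance:
        if 0 <= a < dur_total:
            events.append(GaitEvent("IC", a))
        if 0 <= b < dur_total:
            events.append(GaitEvent("FC", b))
    for (a, b) in contra_stance:
        if 0 <= a < dur_total:
            events.append(GaitEvent("OIC", a))
        if 0 <= b < dur_total:
            events.append(GaitEvent("OFC", b))

    return GaitRecording(
        emg=emg,
        grf_ipsi=grf_ipsi,
        grf_contra=grf_contra,
        fs=cfg.fs,
        muscle_names=tuple(cfg.muscle_names),
        truth_events=GaitEventList(events),
        truth_envelope=envelope,
        config_used=cfg,
        cycle_starts=starts[: n_cycles + 1],
    )


def truth_phase_series(recording: GaitRecording, scheme, fs_out: float | None = None) -> np.ndarray:
    """Per-sample phase labels computed from the stored truth events
    (bypassing GRF detection); covers complete cycles only, -1 elsewhere."""
    from .labeling import phase_labels

    if len(recording.truth_events) == 0:
        raise ValueError("recording has no truth events")
    fs_out = fs_out or recording.fs
    n_out = int(round(recording.n_samples * fs_out / recording.fs))
    return phase_labels(recording.truth_events, n_out, fs_out, scheme)
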