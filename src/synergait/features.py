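"""Per-window EMG feature banks.

Four of the five feature kinds live here; muscle-synergy (MS) features are
in :mod:`synergait.synergy`.

* TD — nine time-domain statistics per channel (MAV, ZC, SSC, WL, four
  Yule-Walker AR coefficients, RMS): 36 values for 4 channels.
* WC — raw discrete-wavelet coefficients (sym7, level 5, Mallat cascade).
* WF — five statistics (energy, variance, std, waveform length, spectral
  entropy of the normalized squared coefficients) per subband:
  5 x (level+1) x channels = 120 values for 4 channels, level 5.
* RE — the raw window samples, sample-major interleaved across muscles:
  muscles x window_len values (1600 for 4 x 400).

All extractors are stateless scikit-learn transformers over a window tensor
of shape (n_windows, muscles, window_len); the module-level functions are
thin single-window wrappers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy.linalg import solve_toeplitz
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TimeDomainFeatures",
    "WaveletCoefficients",
    "WaveletFeatures",
    "RawSamples",
    "td_features",
    "wavelet_coeffs",
    "wavelet_features",
    "raw_features",
]


class _WindowTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer over (n_windows, muscles, window_len) tensors."""

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[np.newaxis]
        if X.ndim != 3:
            raise ValueError("expected window tensor of shape (n_windows, muscles, L)")
        return X

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        out = self._transform_tensor(X)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite feature values produced")
        return out


def _ar_yule_walker(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by Yule-Walker with biased autocovariance.

    Degenerate (constant / zero-variance) channels return zeros.
    """
    n = x.size
    if np.ptp(x) == 0:  # constant channel: the fit is degenerate
        if x[0] != 0:
            warnings.warn("constant channel; AR coefficients set to zero")
        return np.zeros(order)
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= 1e-300:
        return np.zeros(order)
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        warnings.warn("degenerate AR fit; returning zero coefficients")
        return np.zeros(order)
    if not np.all(np.isfinite(a)):
        warnings.warn("degenerate AR fit; returning zero coefficients")
        return np.zeros(order)
    return a


class TimeDomainFeatures(_WindowTransformer):
    """Nine time-domain features per channel, channel-major.

    Per channel: MAV, zero crossings, slope sign changes, waveform length,
    AR(order) coefficients, RMS.  ``eps`` is the dead-zone threshold for the
    ZC/SSC comparators (0 by default; real EMG typically needs a small
    positive value to reject baseline chatter).
    """

    def __init__(self, ar_order: int = 4, eps: float = 0.0):
        self.ar_order = ar_order
        self.eps = eps

    @property
    def n_per_channel(self) -> int:
        return 5 + self.ar_order

    def _transform_tensor(self, X: np.ndarray) -> np.ndarray:
        B, p, L = X.shape
        if L < self.ar_order + 4:
            raise ValueError(f"window too short ({L}) for AR order {self.ar_order}")
        eps = self.eps
        out = np.empty((B, p * self.n_per_channel))
        mav = np.abs(X).mean(axis=2)
        rms = np.sqrt((X**2).mean(axis=2))
        d = np.diff(X, axis=2)
        wl = np.abs(d).sum(axis=2)
        zc = np.sum((X[:, :, :-1] * X[:, :, 1:] < 0) & (np.abs(d) >= eps), axis=2)
        back = X[:, :, 1:-1] - X[:, :, :-2]
        fwd = X[:, :, 1:-1] - X[:, :, 2:]
        ssc = np.sum(
            (back * fwd > 0) & (np.maximum(np.abs(back), np.abs(fwd)) >= eps), axis=2
        )
        for b in range(B):
            for c in range(p):
                ar = _ar_yule_walker(X[b, c], self.ar_order)
                j = c * self.n_per_channel
                out[b, j] = mav[b, c]
                out[b, j + 1] = zc[b, c]
                out[b, j + 2] = ssc[b, c]
                out[b, j + 3] = wl[b, c]
                out[b, j + 4 : j + 4 + self.ar_order] = ar
                out[b, j + 4 + self.ar_order] = rms[b, c]
        return out


class WaveletCoefficients(_WindowTransformer):
    """Flat DWT coefficient vector [A_n, D_n, ..., D_1] per channel.

    Mallat cascade via :func:`pywt.wavedec`; the boundary ``mode`` is part
    of the extraction metadata because it sets the output length.
    """

    def __init__(self, wavelet: str = "sym7", level: int = 5, mode: str = "symmetric"):
        self.wavelet = wavelet
        self.level = level
        self.mode = mode

    def _check_level(self, L: int) -> None:
        flen = pywt.Wavelet(self.wavelet).dec_len
        # admit one level beyond pywt's conservative "useful" bound: a 200 ms
        # window (400 samples) supports the standard sym7 level-5 cascade
        max_level = int(np.floor(np.log2(L / (flen - 1)))) + 1 if L >= flen else 0
        if self.level > max_level:
            raise ValueError(
                f"level {self.level} too deep for length {L}; max admissible is {max_level}"
            )

    def decompose(self, x: np.ndarray) -> list[np.ndarray]:
        self._check_level(x.shape[-1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return pywt.wavedec(x, self.wavelet, mode=self.mode, level=self.level, axis=-1)

    def _transform_tensor(self, X: np.ndarray) -> np.ndarray:
        coeffs = self.decompose(X)  # list of (B, p, len_j)
        B, p = X.shape[:2]
        flat = np.concatenate(coeffs, axis=-1)  # (B, p, total)
        return flat.reshape(B, p * flat.shape[-1])


class WaveletFeatures(_WindowTransformer):
    """Five statistics per DWT subband: energy, variance, standard
    deviation, waveform length, and entropy of p_i = c_i^2 / sum c^2
    (0 log 0 := 0).  Subband-major within channel, channel-major overall:
    5 x (level+1) x channels values."""

    def __init__(self, wavelet: str = "sym7", level: int = 5, mode: str = "symmetric"):
        self.wavelet = wavelet
        self.level = level
        self.mode = mode

    def _transform_tensor(self, X: np.ndarray) -> np.ndarray:
        wc = WaveletCoefficients(self.wavelet, self.level, self.mode)
        coeffs = wc.decompose(X)
        B, p = X.shape[:2]
        n_sub = len(coeffs)
        out = np.empty((B, p, n_sub, 5))
        for j, c in enumerate(coeffs):
            e = (c**2).sum(axis=-1)
            var = c.var(axis=-1)
            std = np.sqrt(var)
            wl = np.abs(np.diff(c, axis=-1)).sum(axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                pmf = c**2 / e[..., None]
                ent = -np.nansum(np.where(pmf > 0, pmf * np.log(pmf), 0.0), axis=-1)
            ent = np.where(e > 0, ent, 0.0)
            out[:, :, j, 0] = e
            out[:, :, j, 1] = var
            out[:, :, j, 2] = std
            out[:, :, j, 3] = wl
            out[:, :, j, 4] = ent
        return out.reshape(B, p * n_sub * 5)


class RawSamples(_WindowTransformer):
    """The window itself as a feature vector, sample-major interleaved:
    (muscle 1..p at sample 1), (muscle 1..p at sample 2), ...  Length
    muscles x window_len; the reshape is a bijection with the window."""

    def _transform_tensor(self, X: np.ndarray) -> np.ndarray:
        B, p, L = X.shape
        return X.transpose(0, 2, 1).reshape(B, L * p)


def td_features(window: np.ndarray, ar_order: int = 4, eps: float = 0.0) -> np.ndarray:
    return TimeDomainFeatures(ar_order=ar_order, eps=eps).transform(window)[0]


def wavelet_coeffs(window: np.ndarray, wavelet: str = "sym7", level: int = 5,
                   mode: str = "symmetric") -> np.ndarray:
    return WaveletCoefficients(wavelet, level, mode).transform(window)[0]


def wavelet_features(window: np.ndarray, wavelet: str = "sym7", level: int = 5,
                     mode: str = "symmetric") -> np.ndarray:
    return WaveletFeatures(wavelet, level, mode).transform(window)[0]


def raw_features(window: np.ndarray) -> np.ndarray:
    return RawSamples().transform(window)[0]
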