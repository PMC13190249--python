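"""Welch PSD, magnitude-squared coherence, shuffle confidence limit, band AUC.

The magnitude-squared coherence (MSC) between two conditioned LFPs x, y is

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))

estimated by Welch averaging over 3-s, 50 %-overlap Hamming-tapered
windows of the 0-100 Hz band-passed signals.  Because a finite window
count biases MSC upward under independence, significance is judged
against a Monte-Carlo surrogate: the region-A windows are shuffled
(sample permutation within each window, destroying all temporal
structure while preserving the amplitude distribution), MSC is
recomputed, and the 95th percentile of the pooled surrogate
distribution serves as per-frequency confidence limit.  Band-limited
coupling is summarised as the trapezoidal area under the MSC curve over
the low-theta band (3-5 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording
from .preprocess import EDGE_EXCLUDE_S, bandpass

__all__ = [
    "PSDResult",
    "CoherenceResult",
    "welch_psd",
    "msc",
    "shuffle_confidence",
    "band_auc",
    "fold_change",
    "FoldChangeResult",
]

LOW_THETA_BAND = (3.0, 5.0)
MSC_WINDOW_S = 3.0
MSC_BROADBAND = (0.0, 100.0)


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray  # units^2 / Hz
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    msc: np.ndarray
    n_windows: int
    conf_limit: np.ndarray | None = None
    band: tuple[float, float] = LOW_THETA_BAND
    band_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if np.any((self.msc < -1e-12) | (self.msc > 1 + 1e-9)):
            raise ValueError("MSC outside [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)
        self.band_auc = band_auc(self, *self.band)


def welch_psd(rec: Recording, channel: int = 0, window_s: float = 10.0,
              overlap: float = 0.5) -> PSDResult:
    """Welch PSD with a 10-s Hamming window and 50 % overlap (density scaling)."""
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < 2 * nperseg * (1 - overlap) + nperseg * overlap:
        raise ValueError("signal shorter than two analysis windows")
    freqs, pxx = sps.welch(
        rec.signal[channel], fs=rec.fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend=False, scaling="density",
    )
    return PSDResult(freqs=freqs, power=pxx, window_s=window_s, overlap=overlap)


# ---------------------------------------------------------------------------
# windowed-FFT machinery shared by the coherence estimator and its surrogate
# ---------------------------------------------------------------------------

def _prepare_pair(recA: Recording, recB: Recording, chA: int, chB: int,
                  window_s: float, band: tuple[float, float] | None,
                  edge_s: float) -> tuple[np.ndarray, np.ndarray, float, int]:
    if recA.fs != recB.fs:
        raise ValueError("recordings must share a sampling rate")
    if recA.n_samples != recB.n_samples:
        raise ValueError("recordings must share a duration")
    fs = recA.fs
    if band is not None:
        recA = bandpass(recA, *band) if band[1] < fs / 2 else recA
        recB = bandpass(recB, *band) if band[1] < fs / 2 else recB
    x = recA.signal[chA]
    y = recB.signal[chB]
    n_edge = int(round(edge_s * fs))
    if n_edge:
        x = x[n_edge:-n_edge]
        y = y[n_edge:-n_edge]
    nperseg = int(round(window_s * fs))
    return x, y, fs, nperseg


def _segments(x: np.ndarray, nperseg: int, hop: int) -> np.ndarray:
    n_win = (x.size - nperseg) // hop + 1
    idx = hop * np.arange(n_win)[:, None] + np.arange(nperseg)[None, :]
    return x[idx]


def _msc_from_ffts(fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    pxx = np.mean(np.abs(fx) ** 2, axis=0)
    pyy = np.mean(np.abs(fy) ** 2, axis=0)
    pxy = np.mean(fx * np.conj(fy), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / (pxx * pyy)
    return np.nan_to_num(c, nan=0.0)


def msc(recA: Recording, recB: Recording, chA: int = 0, chB: int = 0,
        window_s: float = MSC_WINDOW_S, band: tuple[float, float] | None = MSC_BROADBAND,
        edge_s: float = EDGE_EXCLUDE_S,
        conf_limit: np.ndarray | None = None) -> CoherenceResult:
    """Welch-averaged MSC on 3-s, 50 %-overlap windows of 0-100 Hz signals.

    A single window makes MSC degenerate (identically 1); at least 8
    windows are required.
    """
    x, y, fs, nperseg = _prepare_pair(recA, recB, chA, chB, window_s, band, edge_s)
    hop = nperseg // 2
    n_windows = (x.size - nperseg) // hop + 1
    if n_windows < 8:
        raise ValueError(f"only {n_windows} analysis windows; need >= 8")
    taper = sps.get_window("hamming", nperseg)
    fx = np.fft.rfft(_segments(x, nperseg, hop) * taper, axis=1)
    fy = np.fft.rfft(_segments(y, nperseg, hop) * taper, axis=1)
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    return CoherenceResult(freqs=freqs, msc=_msc_from_ffts(fx, fy),
                           n_windows=n_windows, conf_limit=conf_limit)


def shuffle_confidence(recA: Recording, recB: Recording, chA: int = 0, chB: int = 0,
                       n_iter: int = 100, quantile: float = 0.95,
                       window_s: float = MSC_WINDOW_S,
                       band: tuple[float, float] | None = MSC_BROADBAND,
                       edge_s: float = EDGE_EXCLUDE_S,
                       method: str = "permute",
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-frequency surrogate confidence limit for the MSC.

    Each iteration destroys the temporal structure of the region-A
    signal within every contiguous 3-s block (``method='permute'``:
    random sample permutation; ``method='shift'``: random circular time
    shift), leaves region B intact, re-windows the shuffled signal with
    the same 50 % overlap, and recomputes the Welch-averaged MSC.  The
    requested quantile of the pooled surrogate distribution is returned
    per frequency.

    Shuffling the continuous signal in place (rather than each
    overlapping analysis window independently) preserves the estimator's
    window-overlap correlation structure, which the null distribution of
    the true MSC also carries; destroying it makes the limit too tight.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if n_iter < 10:
        warnings.warn(f"n_iter={n_iter} gives a coarse quantile estimate",
                      stacklevel=2)
    if method not in ("permute", "shift"):
        raise ValueError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng(rng)

    x, y, fs, nperseg = _prepare_pair(recA, recB, chA, chB, window_s, band, edge_s)
    hop = nperseg // 2
    n_windows = (x.size - nperseg) // hop + 1
    if n_windows < 8:
        raise ValueError(f"only {n_windows} analysis windows; need >= 8")
    taper = sps.get_window("hamming", nperseg)
    fy = np.fft.rfft(_segments(y, nperseg, hop) * taper, axis=1)

    n_blocks = x.size // nperseg
    blocks = x[:n_blocks * nperseg].reshape(n_blocks, nperseg)
    tail = x[n_blocks * nperseg:]

    surr = np.empty((n_iter, nperseg // 2 + 1))
    for it in range(n_iter):
        if method == "permute":
            sb = rng.permuted(blocks, axis=1)
        else:
            shifts = rng.integers(1, nperseg, size=n_blocks)
            cols = (np.arange(nperseg)[None, :] + shifts[:, None]) % nperseg
            sb = np.take_along_axis(blocks, cols, axis=1)
        sx = np.concatenate([sb.ravel(), tail])
        fx = np.fft.rfft(_segments(sx, nperseg, hop) * taper, axis=1)
        surr[it] = _msc_from_ffts(fx, fy)
    return np.quantile(surr, quantile, axis=0)


def band_auc(result: CoherenceResult | tuple[np.ndarray, np.ndarray],
             lo: float = LOW_THETA_BAND[0], hi: float = LOW_THETA_BAND[1]) -> float:
    """Trapezoidal area under the MSC curve over ``[lo, hi]`` Hz.

    The band edges are linearly interpolated onto the frequency grid, so
    the integral covers exactly the requested band.
    """
    if isinstance(result, CoherenceResult):
        freqs, m = result.freqs, result.msc
    else:
        freqs, m = np.asarray(result[0], float), np.asarray(result[1], float)
    if lo < freqs[0] or hi > freqs[-1] or lo >= hi:
        raise ValueError(f"band [{lo}, {hi}] outside frequency grid")
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inside], [hi]])
    v = np.concatenate([[np.interp(lo, freqs, m)], m[inside],
                        [np.interp(hi, freqs, m)]])
    return float(np.trapezoid(v, f))


@dataclass
class FoldChangeResult:
    folds: np.ndarray
    median: float
    iqr: float
    young_mean: float


def fold_change(auc_young: np.ndarray, auc_old: np.ndarray) -> FoldChangeResult:
    """Developmental fold change: each older-animal AUC over the young-group mean.

    Cross-sectional convention (different animals at the two ages);
    summarised as median (IQR).
    """
    young = np.asarray(auc_young, dtype=float)
    old = np.asarray(auc_old, dtype=float)
    if young.size == 0 or old.size == 0:
        raise ValueError("both age groups must be non-empty")
    if np.any(young <= 0) or np.any(old <= 0):
        raise ValueError("band AUC values must be positive")
    folds = old / young.mean()
    q1, q3 = np.percentile(folds, [25, 75])
    return FoldChangeResult(folds=folds, median=float(np.median(folds)),
                            iqr=float(q3 - q1), young_mean=float(young.mean()))
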