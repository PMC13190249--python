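"""Single-unit firing statistics, waveform features, RS/FS classification, QC.

Firing variability is quantified by the Fano factor (variance over mean
of spike counts in non-overlapping bins; 1 for a Poisson process).
Waveform features are the valley-to-peak time (trough to subsequent
positive peak, a proxy for the medium afterhyperpolarisation duration)
and the full width at half maximum of the initial negative trough; both
use parabolic sub-sample interpolation.  Units are classified
fast-spiking (putative inhibitory) when *both* features fall strictly
below 0.3 ms, regular-spiking otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SpikeTrain, UnitWaveform

__all__ = [
    "FiringMetrics",
    "WaveformFeatures",
    "UnitMetrics",
    "firing_metrics",
    "waveform_features",
    "classify_unit",
    "compute_unit_metrics",
    "snr_from_waveform",
    "isolation_metrics",
    "isi_violation_fraction",
    "qc_filter",
    "log_rate_histogram",
    "rate_width_correlation",
]

FS_THRESHOLD_MS = 0.3
SNR_THRESHOLDS = {"openephys": 5.0, "neuralynx": 11.0}
ISOLATION_DISTANCE_MIN = 25.0
L_RATIO_MAX = 0.5
REFRACTORY_MS = 1.0


@dataclass
class FiringMetrics:
    mean_rate: float
    fano: float | None  # None when undefined (no spikes)
    n_spikes: int
    bin_s: float


@dataclass
class WaveformFeatures:
    valley_to_peak_ms: float | None
    fwhm_ms: float | None
    defined: bool
    reason: str | None = None


@dataclass
class UnitMetrics:
    unit_id: str
    mean_rate: float
    fano: float | None
    valley_to_peak_ms: float | None
    fwhm_ms: float | None
    cell_class: str | None
    qc: dict


def firing_metrics(train: SpikeTrain, bin_s: float = 1.0) -> FiringMetrics:
    """Mean rate (spikes/s) and Fano factor over non-overlapping count bins."""
    if train.recording_duration < 10 * bin_s:
        raise ValueError("recording shorter than 10 count bins")
    n_bins = int(train.recording_duration // bin_s)
    counts, _ = np.histogram(train.spike_times, bins=n_bins,
                             range=(0, n_bins * bin_s))
    rate = train.n_spikes / train.recording_duration
    if train.n_spikes == 0 or counts.mean() == 0:
        return FiringMetrics(mean_rate=rate, fano=None,
                             n_spikes=train.n_spikes, bin_s=bin_s)
    fano = float(np.var(counts, ddof=1) / counts.mean())
    return FiringMetrics(mean_rate=rate, fano=fano,
                         n_spikes=train.n_spikes, bin_s=bin_s)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum position and value from a 3-point parabola."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i), float(y[i])
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    off = float(np.clip(off, -0.5, 0.5))
    val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * off
    return i + off, float(val)


def waveform_features(wf: UnitWaveform, peak_search_ms: float = 2.0) -> WaveformFeatures:
    """Valley-to-peak time and trough FWHM of a mean extracellular waveform.

    The baseline is the median of the pre-trough samples; FWHM is the
    width of the trough at half its depth below baseline, with linear
    interpolation at the half-depth crossings.  The rebound peak must be
    an interior local maximum within ``peak_search_ms`` after the trough.
    """
    w = wf.samples
    fs = wf.fs
    trough = int(np.argmin(w))
    baseline = float(np.median(w[:trough])) if trough > 0 else 0.0
    t_pos, t_val = _parabolic_refine(w, trough)
    depth = baseline - t_val
    if depth <= 0:
        return WaveformFeatures(None, None, False, "no trough below baseline")

    # --- valley-to-peak ---------------------------------------------------
    n_search = int(round(peak_search_ms * 1e-3 * fs))
    seg = w[trough: trough + n_search + 1]
    if seg.size < 3:
        return WaveformFeatures(None, None, False, "waveform ends at trough")
    rel_peak = int(np.argmax(seg[1:])) + 1
    if rel_peak >= seg.size - 1 and (w.size <= trough + rel_peak + 1
                                     or w[trough + rel_peak + 1] > w[trough + rel_peak]):
        return WaveformFeatures(None, None, False,
                                f"no rebound peak within {peak_search_ms} ms")
    p_pos, _ = _parabolic_refine(w, trough + rel_peak)
    v2p_ms = (p_pos - t_pos) / fs * 1e3

    # --- FWHM of the trough -----------------------------------------------
    half = baseline - depth / 2
    left = None
    for i in range(trough, 0, -1):
        if w[i - 1] >= half > w[i]:
            left = (i - 1) + (w[i - 1] - half) / (w[i - 1] - w[i])
            break
    right = None
    for i in range(trough, w.size - 1):
        if w[i] < half <= w[i + 1]:
            right = i + (half - w[i]) / (w[i + 1] - w[i])
            break
    if left is None or right is None:
        return WaveformFeatures(float(v2p_ms), None, False,
                                "trough does not recross half depth")
    fwhm_ms = (right - left) / fs * 1e3
    return WaveformFeatures(float(v2p_ms), float(fwhm_ms), True)


def classify_unit(valley_to_peak_ms: float, fwhm_ms: float,
                  threshold_ms: float = FS_THRESHOLD_MS) -> str:
    """``fast_spiking`` iff both features are strictly below 0.3 ms."""
    if valley_to_peak_ms is None or fwhm_ms is None:
        raise ValueError("both waveform features must be defined")
    if fwhm_ms < threshold_ms and valley_to_peak_ms < threshold_ms:
        return "fast_spiking"
    return "regular_spiking"


def compute_unit_metrics(train: SpikeTrain, wf: UnitWaveform | None = None,
                         bin_s: float = 1.0, qc: dict | None = None) -> UnitMetrics:
    fm = firing_metrics(train, bin_s=bin_s)
    v2p = fwhm = cls = None
    if wf is not None:
        feats = waveform_features(wf)
        if feats.defined:
            v2p, fwhm = feats.valley_to_peak_ms, feats.fwhm_ms
            cls = classify_unit(v2p, fwhm)
    return UnitMetrics(unit_id=train.unit_id, mean_rate=fm.mean_rate, fano=fm.fano,
                       valley_to_peak_ms=v2p, fwhm_ms=fwhm, cell_class=cls,
                       qc=dict(qc or {}))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def snr_from_waveform(template: np.ndarray, residual_sd: float) -> float:
    """Peak-to-peak template amplitude over twice the residual noise SD."""
    if residual_sd <= 0:
        return np.inf
    return float(np.ptp(template) / (2 * residual_sd))


def isolation_metrics(unit_points: np.ndarray, other_points: np.ndarray
                      ) -> tuple[float, float]:
    """Isolation Distance and L-Ratio from feature-space points.

    Mahalanobis distances of non-member points are computed with respect
    to the unit cluster's mean and covariance.  Isolation Distance is
    the squared distance of the n-th closest non-member (n = cluster
    size); L-Ratio is ``sum(chi2.sf(D^2, df)) / n`` over non-members.
    """
    u = np.atleast_2d(np.asarray(unit_points, float))
    o = np.atleast_2d(np.asarray(other_points, float))
    n, df = u.shape
    if n <= df:
        raise ValueError("need more cluster points than feature dimensions")
    mean = u.mean(axis=0)
    cov = np.cov(u, rowvar=False)
    cov = np.atleast_2d(cov)
    d = o - mean
    d2 = np.einsum("ij,jk,ik->i", d, np.linalg.pinv(cov), d)
    d2_sorted = np.sort(d2)
    iso = float(d2_sorted[n - 1]) if o.shape[0] >= n else float("inf")
    l_ratio = float(np.sum(stats.chi2.sf(d2, df)) / n)
    return iso, l_ratio


def isi_violation_fraction(train: SpikeTrain,
                           refractory_ms: float = REFRACTORY_MS) -> float:
    if train.n_spikes < 2:
        return 0.0
    return float(np.mean(train.isis() < refractory_ms * 1e-3))


def qc_filter(units: list[dict], source: str,
              isi_tolerance: float = 0.0) -> tuple[list[dict], list[dict]]:
    """Accept units passing SNR, isolation, L-ratio and refractory criteria.

    Each entry needs a ``qc`` dict with ``snr``, ``isolation_distance``,
    ``l_ratio`` and either ``isi_violation_fraction`` or a ``train``
    (SpikeTrain) to compute it from.  Returns the accepted entries and a
    rejection log with reasons.
    """
    if source not in SNR_THRESHOLDS:
        raise ValueError(f"unknown acquisition source {source!r}")
    snr_min = SNR_THRESHOLDS[source]
    accepted, rejected = [], []
    for u in units:
        qc = u.get("qc")
        uid = u.get("unit_id", "?")
        if qc is None or not {"snr", "isolation_distance", "l_ratio"} <= qc.keys():
            rejected.append({"unit_id": uid, "reasons": ["unscored"]})
            continue
        viol = qc.get("isi_violation_fraction")
        if viol is None:
            train = u.get("train")
            if train is None:
                rejected.append({"unit_id": uid, "reasons": ["unscored"]})
                continue
            viol = isi_violation_fraction(train)
        reasons = []
        if not qc["snr"] >= snr_min:
            reasons.append(f"snr {qc['snr']:.2f} < {snr_min}")
        if not qc["isolation_distance"] > ISOLATION_DISTANCE_MIN:
            reasons.append(f"isolation_distance {qc['isolation_distance']:.2f} <= "
                           f"{ISOLATION_DISTANCE_MIN}")
        if not qc["l_ratio"] < L_RATIO_MAX:
            reasons.append(f"l_ratio {qc['l_ratio']:.3f} >= {L_RATIO_MAX}")
        if viol > isi_tolerance:
            reasons.append(f"isi violations {viol:.4f} > {isi_tolerance}")
        if reasons:
            rejected.append({"unit_id": uid, "reasons": reasons})
        else:
            accepted.append(u)
    return accepted, rejected


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

@dataclass
class LogRateHistogram:
    edges: np.ndarray  # log10(rate) bin edges
    counts: np.ndarray
    n_excluded: int


def log_rate_histogram(rates: np.ndarray, bin_width: float = 0.3) -> LogRateHistogram:
    """Counts over log10(firing rate) bins of the given width.

    Zero or negative rates cannot be placed on a log axis and are
    excluded (their count is reported).  The leftmost edge sits at the
    floor of the minimum log10 rate.
    """
    r = np.asarray(rates, dtype=float)
    pos = r[r > 0]
    n_excluded = r.size - pos.size
    if pos.size == 0:
        raise ValueError("no positive rates to histogram")
    logr = np.log10(pos)
    left = np.floor(logr.min())
    n_bins = int(np.ceil((logr.max() - left) / bin_width)) + 1
    edges = left + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(logr, bins=edges)
    return LogRateHistogram(edges=edges, counts=counts, n_excluded=n_excluded)


def rate_width_correlation(rates: np.ndarray, fwhms: np.ndarray
                           ) -> tuple[float | None, float | None]:
    """Spearman rank correlation between firing rate and spike half-width."""
    r = np.asarray(rates, float)
    w = np.asarray(fwhms, float)
    if r.size != w.size or r.size < 5:
        raise ValueError("need >= 5 paired (rate, fwhm) values")
    if np.all(r == r[0]) or np.all(w == w[0]):
        return None, None  # correlation undefined for constant input
    rho, p = stats.spearmanr(r, w)
    return float(rho), float(p)
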