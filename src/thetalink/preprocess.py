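"""LFP conditioning chain: wideband signal to analysis-ready 2 kHz LFP.

All filters are applied zero-phase (forward-backward), so the effective
order doubles relative to the nominal Butterworth order.  Phase locking
downstream depends on phase-neutral preprocessing, which makes the
two-pass choice mandatory rather than cosmetic.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = ["condition_lfp", "highpass_spikeband", "bandpass"]

#: seconds excluded from window statistics at each end downstream
EDGE_EXCLUDE_S = 1.0

LFP_FS = 2000.0
LFP_LOWPASS_HZ = 1000.0
NOTCH_HZ = 50.0
NOTCH_Q = 30.0
SPIKEBAND_HZ = 400.0


def _with_signal(rec: Recording, sig: np.ndarray, fs: float | None = None) -> Recording:
    return Recording(signal=sig, fs=rec.fs if fs is None else fs,
                     channel_meta=[dict(m) for m in rec.channel_meta])


def condition_lfp(
    rec: Recording,
    fs_out: float = LFP_FS,
    lowpass_hz: float = LFP_LOWPASS_HZ,
    order: int = 3,
    notch_hz: float | None = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
) -> Recording:
    """Low-pass (<1 kHz, 3rd-order Butterworth), resample to 2 kHz, notch 50 Hz.

    The input must be sampled fast enough that the low-pass band is
    honest (``fs >= 2 * lowpass_hz``) and that the resampling is a
    decimation (``fs >= fs_out``).
    """
    if rec.fs < fs_out:
        raise ValueError(
            f"fs={rec.fs} Hz below the {fs_out} Hz target rate (aliasing)")
    if lowpass_hz < rec.fs / 2:
        sos = sps.butter(order, lowpass_hz, btype="low", fs=rec.fs, output="sos")
        sig = sps.sosfiltfilt(sos, rec.signal, axis=1)
    elif rec.fs != fs_out:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {lowpass_hz} Hz low-pass (aliasing)")
    else:
        # already at the target rate with the cutoff at Nyquist: no-op band
        sig = rec.signal

    if rec.fs != fs_out:
        frac = Fraction(int(round(fs_out)), int(round(rec.fs)))
        sig = sps.resample_poly(sig, frac.numerator, frac.denominator, axis=1)

    if notch_hz is not None and notch_hz > 0:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=fs_out)
        sig = sps.filtfilt(b, a, sig, axis=1)

    return _with_signal(rec, sig, fs=fs_out)


def highpass_spikeband(rec: Recording, cutoff_hz: float = SPIKEBAND_HZ,
                       order: int = 2) -> Recording:
    """High-pass (>400 Hz, 2nd-order Butterworth) path for spike waveforms."""
    if rec.fs < 2000:
        raise ValueError(f"fs={rec.fs} Hz too low for the >{cutoff_hz} Hz spike band")
    sos = sps.butter(order, cutoff_hz, btype="high", fs=rec.fs, output="sos")
    return _with_signal(rec, sps.sosfiltfilt(sos, rec.signal, axis=1))


def bandpass(rec: Recording, lo: float, hi: float, order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass; ``lo == 0`` degenerates to a low-pass."""
    if not (0 <= lo < hi):
        raise ValueError(f"invalid band [{lo}, {hi}]")
    if hi >= rec.fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    if lo == 0:
        sos = sps.butter(order, hi, btype="low", fs=rec.fs, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="band", fs=rec.fs, output="sos")
    return _with_signal(rec, sps.sosfiltfilt(sos, rec.signal, axis=1))
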