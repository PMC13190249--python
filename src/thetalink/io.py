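"""Core data containers and on-disk formats.

Continuous signals travel as :class:`Recording` (HDF5 container, dataset
``signal`` of shape ``channels x samples`` plus scalar attributes), spike
timestamps as :class:`SpikeTrain` (CSV with columns ``unit_id,
spike_time_s, channel, region``) and mean extracellular waveforms as
:class:`UnitWaveform` (HDF5, one dataset per unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SpikeTrain",
    "UnitWaveform",
    "load_recording",
    "save_recording",
    "load_spike_trains",
    "save_spike_trains",
    "load_waveforms",
    "save_waveforms",
]

#: minimum separation below which two timestamps count as duplicates (s)
DUPLICATE_TOL_S = 1e-4


@dataclass
class Recording:
    """Multi-channel continuous signal with sampling rate and metadata.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)``; a 1-D array is
        promoted to a single channel.
    fs
        Sampling rate in Hz, strictly positive.
    channel_meta
        One dict per channel; free-form keys, conventionally ``region``
        (PL / IL / BLAa or a synthetic label), ``layer``, ``subject``,
        ``group``, ``sex``, ``age_class``.
    """

    signal: np.ndarray
    fs: float
    channel_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2:
            raise ValueError("signal must be 1-D or 2-D (channels x samples)")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if not self.channel_meta:
            self.channel_meta = [{} for _ in range(self.n_channels)]
        if len(self.channel_meta) != self.n_channels:
            raise ValueError(
                f"channel_meta has {len(self.channel_meta)} entries "
                f"for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit.

    Times are seconds from recording onset, strictly inside
    ``[0, recording_duration]``, sorted ascending, with no duplicates
    closer than 0.1 ms.
    """

    unit_id: str
    spike_times: np.ndarray
    recording_duration: float
    region: str = ""
    channel: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float).ravel()
        if t.size and (t.min() < 0 or t.max() > self.recording_duration):
            raise ValueError("spike times outside [0, recording_duration]")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted ascending")
        if np.any(np.diff(t) < DUPLICATE_TOL_S):
            raise ValueError("duplicate spike times (< 0.1 ms apart)")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.recording_duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass
class UnitWaveform:
    """Mean extracellular spike waveform of one unit.

    Must span at least 2 ms and contain exactly one global minimum
    (the trough), whose index is ``alignment``.
    """

    unit_id: str
    samples: np.ndarray
    fs: float
    alignment: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(w)):
            raise ValueError("waveform contains non-finite samples")
        if w.size / self.fs < 2e-3:
            raise ValueError("waveform must span at least 2 ms")
        trough = int(np.argmin(w))
        if np.sum(w == w[trough]) != 1:
            raise ValueError("waveform must have exactly one global minimum")
        if self.alignment is None:
            self.alignment = trough
        self.samples = w

    @property
    def duration_ms(self) -> float:
        return 1e3 * self.samples.size / self.fs


# ---------------------------------------------------------------------------
# HDF5 / CSV round trips
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["fs"] = rec.fs
        f.attrs["channel_meta"] = json.dumps(rec.channel_meta)
    return path


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        signal = f["signal"][()]
        fs = float(f.attrs["fs"])
        meta = json.loads(f.attrs.get("channel_meta", "[]"))
    return Recording(signal=signal, fs=fs, channel_meta=meta)


def save_spike_trains(trains: list[SpikeTrain], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append(
                {"unit_id": tr.unit_id, "spike_time_s": t,
                 "channel": tr.channel, "region": tr.region}
            )
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s", "channel", "region"])
    df.to_csv(path, index=False)
    return path


def load_spike_trains(path: str | Path, recording_duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        times = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        trains.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times=times,
                recording_duration=recording_duration,
                region=str(grp["region"].iloc[0]) if "region" in grp else "",
                channel=int(grp["channel"].iloc[0]) if "channel" in grp else 0,
            )
        )
    return trains


def save_waveforms(waveforms: list[UnitWaveform], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for wf in waveforms:
            d = f.create_dataset(str(wf.unit_id), data=wf.samples)
            d.attrs["fs"] = wf.fs
            d.attrs["alignment"] = wf.alignment
    return path


def load_waveforms(path: str | Path) -> list[UnitWaveform]:
    out = []
    with h5py.File(path, "r") as f:
        for uid in sorted(f.keys()):
            d = f[uid]
            out.append(
                UnitWaveform(
                    unit_id=uid,
                    samples=d[()],
                    fs=float(d.attrs["fs"]),
                    alignment=int(d.attrs["alignment"]),
                )
            )
    return out
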