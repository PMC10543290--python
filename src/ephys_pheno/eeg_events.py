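"""Epileptiform spike detection and spike-train grouping for EEG.

Spikes are high-amplitude transients standing clear of the ongoing EEG.  The
detector band-passes the signal to 1-70 Hz, estimates a robust baseline scale
(1.4826 x median absolute deviation, so the spikes themselves do not inflate
the threshold), and flags local extrema whose absolute amplitude exceeds
``threshold_sd`` baseline units.  Events within a refractory window of a
larger event are suppressed, which collapses the two lobes of a biphasic
transient into a single detection.

Trains are formed by single-linkage clustering in time: consecutive spikes
closer than ``max_gap_s`` join one train, and clusters with fewer than
``min_spikes`` members are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io_formats import SignalRecording

__all__ = [
    "SpikeEvent",
    "SpikeTrain",
    "detect_spikes",
    "group_spike_trains",
    "spike_train_summary",
]


@dataclass(frozen=True)
class SpikeEvent:
    time_s: float
    amplitude_uv: float  # signed peak amplitude of the band-passed signal


@dataclass(frozen=True)
class SpikeTrain:
    onset_s: float
    offset_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def detect_spikes(
    recording: SignalRecording,
    threshold_sd: float = 5.0,
    refractory_s: float = 0.05,
) -> list[SpikeEvent]:
    """Detect high-amplitude transient events in the EEG channel.

    A flat (zero-variance) signal yields an empty list with a warning rather
    than an error, so batch runs over quiet recordings do not abort.
    """
    if threshold_sd <= 0:
        raise ValidationError("threshold_sd must be > 0")
    fs = recording.sampling_rate_hz
    sos = sps.butter(4, [1.0, 70.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, recording.eeg)

    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sigma == 0:
        warnings.warn("flat EEG signal: no spikes detectable")
        return []

    height = threshold_sd * sigma
    peaks, props = sps.find_peaks(np.abs(x), height=height)
    if len(peaks) == 0:
        return []

    # refractory suppression: greedily keep the largest events
    amps = np.abs(x[peaks])
    order = np.argsort(-amps)
    kept_times: list[float] = []
    kept_idx: list[int] = []
    refr = refractory_s
    for i in order:
        t = peaks[i] / fs
        if all(abs(t - kt) >= refr for kt in kept_times):
            kept_times.append(t)
            kept_idx.append(peaks[i])
    kept_idx.sort()
    return [SpikeEvent(time_s=i / fs, amplitude_uv=float(x[i])) for i in kept_idx]


def group_spike_trains(
    spikes: list[SpikeEvent],
    max_gap_s: float = 2.0,
    min_spikes: int = 3,
) -> list[SpikeTrain]:
    """Cluster time-sorted spikes into trains by single linkage in time."""
    if not spikes:
        return []
    times = np.array([s.time_s for s in spikes])
    if np.any(np.diff(times) < 0):
        raise ValidationError("spikes must be time-sorted")
    breaks = np.flatnonzero(np.diff(times) > max_gap_s)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(times) - 1]
    trains = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_spikes:
            trains.append(
                SpikeTrain(onset_s=float(times[s]), offset_s=float(times[e]), n_spikes=n)
            )
    return trains


def spike_train_summary(trains: list[SpikeTrain], recording_duration_s: float) -> dict:
    """Per-recording summary: train count, rate, mean duration, total spikes.

    ``mean_duration_s`` is NaN (reported as missing) when there are no trains.
    """
    n = len(trains)
    return {
        "train_count": n,
        "trains_per_hour": n / (recording_duration_s / 3600.0),
        "mean_duration_s": float(np.mean([t.duration_s for t in trains])) if n else float("nan"),
        "total_spikes": int(sum(t.n_spikes for t in trains)),
    }
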