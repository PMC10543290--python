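"""Rule-based four-state vigilance scoring from EEG, EMG and activity.

Each fixed-length epoch is scored as one of four states using EEG band
powers, EMG tone and locomotor activity:

1. high EMG and activity above the movement noise floor -> ``ACTIVE_WAKE``
2. high EMG alone -> ``WAKE``
3. low EMG with a theta/delta power ratio above threshold -> ``PARADOXICAL``
   (REM-like sleep: muscle atonia with theta-dominant EEG)
4. otherwise -> ``SWS`` (slow-wave sleep: low tone, delta-dominant EEG)

Thresholds are per-recording, so implant-gain differences between animals do
not matter.  The EMG cut defaults to a bimodal split of the epoch EMG RMS
distribution (Otsu's criterion on the log scale, separating the muscle-tone
cluster of wake epochs from the atonia cluster of sleep epochs); a fixed
percentile of the distribution is available as an alternative but couples
the threshold to the animal's realized wake/sleep occupancy.  The activity
cut is a noise-floor estimate (median + 5 scaled-MAD of epoch mean
activity).  The scorer is deterministic given features and thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_spectral import _welch_array, _integrate
from .errors import ValidationError
from .io_formats import SignalRecording

__all__ = [
    "Hypnogram",
    "StateSummary",
    "epoch_features",
    "score_epochs",
    "state_percentages",
]

_STATES = ("ACTIVE_WAKE", "WAKE", "SWS", "PARADOXICAL")


@dataclass
class Hypnogram:
    epoch_len_s: float
    labels: list[str]
    features: pd.DataFrame | None = None
    n_unscorable: int = 0

    def __post_init__(self):
        bad = set(self.labels) - set(_STATES)
        if bad:
            raise ValidationError(f"unknown vigilance states: {sorted(bad)}")


@dataclass
class StateSummary:
    percent_active_wake: float
    percent_wake: float
    percent_sws: float
    percent_paradoxical: float

    def as_dict(self) -> dict:
        return {
            "percent_active_wake": self.percent_active_wake,
            "percent_wake": self.percent_wake,
            "percent_sws": self.percent_sws,
            "percent_paradoxical": self.percent_paradoxical,
        }


def epoch_features(
    recording: SignalRecording,
    epoch_len_s: float = 10.0,
    welch_window_s: float = 2.0,
) -> pd.DataFrame:
    """Per-epoch scoring features.

    Columns: ``epoch, start_s, delta_power, theta_power, theta_delta_ratio,
    emg_rms, activity_mean``.  Band powers come from a Welch PSD of the
    epoch's EEG (2 s Hann windows, 50% overlap); the ratio is NaN when delta
    power is zero.
    """
    if epoch_len_s < welch_window_s:
        raise ValidationError(
            f"epoch_len_s ({epoch_len_s}) must be >= one Welch window "
            f"({welch_window_s} s)"
        )
    fs = recording.sampling_rate_hz
    fs_act = recording.activity_sampling_rate_hz
    spe = int(round(epoch_len_s * fs))
    spe_act = int(round(epoch_len_s * fs_act))
    n_epochs = int(len(recording.eeg) // spe)

    rows = []
    for k in range(n_epochs):
        eeg = recording.eeg[k * spe : (k + 1) * spe]
        emg = recording.emg[k * spe : (k + 1) * spe]
        act = recording.activity[k * spe_act : (k + 1) * spe_act]
        freqs, psd, _, _ = _welch_array(
            eeg, fs, welch_window_s, 0.5, reject_artifacts=False
        )
        delta = _integrate(freqs, psd, 0.5, 4.0)
        theta = _integrate(freqs, psd, 5.0, 9.0)
        rows.append(
            {
                "epoch": k,
                "start_s": k * epoch_len_s,
                "delta_power": delta,
                "theta_power": theta,
                "theta_delta_ratio": theta / delta if delta > 0 else np.nan,
                "emg_rms": float(np.sqrt(np.mean(emg**2))),
                "activity_mean": float(np.mean(act)) if len(act) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _noise_floor(values: np.ndarray) -> float:
    """Movement threshold: median + 5 scaled-MAD of epoch mean activity."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + 5 * 1.4826 * mad + 1e-12


def _otsu_split(values: np.ndarray) -> float:
    """Threshold separating a bimodal sample by maximum between-class variance.

    Applied to log EMG RMS, this finds the gap between the sleep (atonia) and
    wake (muscle tone) clusters regardless of how much of the recording the
    animal spent in each — a fixed percentile cannot do that.
    """
    x = np.sort(values)
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return float(x[-1]) if n else 0.0
    best_k, best_score = 1, -np.inf
    csum = np.cumsum(x)
    total = csum[-1]
    for k in range(1, n):  # k values in the lower class
        m0 = csum[k - 1] / k
        m1 = (total - csum[k - 1]) / (n - k)
        score = k * (n - k) * (m0 - m1) ** 2
        if score > best_score:
            best_score, best_k = score, k
    return float((x[best_k - 1] + x[best_k]) / 2)


def score_epochs(
    features: pd.DataFrame,
    epoch_len_s: float = 10.0,
    emg_percentile: float | None = None,
    ratio_threshold: float = 1.5,
    emg_threshold: float | None = None,
    activity_threshold: float | None = None,
    smooth: bool = False,
) -> Hypnogram:
    """Apply the four decision rules, in order, to every epoch.

    The EMG threshold resolves in priority order: an explicit
    ``emg_threshold`` (µV RMS), an ``emg_percentile`` of the epoch EMG RMS
    distribution, or (default) the Otsu bimodal split on log EMG RMS.

    Epochs with missing EMG or band-power features cannot be scored; they are
    labeled ``WAKE`` and counted in ``Hypnogram.n_unscorable``.  Optional
    majority-vote smoothing over 3 epochs is off by default so state
    percentages stay unbiased.
    """
    emg = features["emg_rms"].to_numpy(dtype=float)
    act = features["activity_mean"].to_numpy(dtype=float)
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)

    if emg_threshold is None:
        finite = emg[np.isfinite(emg)]
        if emg_percentile is not None:
            emg_threshold = float(np.percentile(finite, emg_percentile))
        elif len(finite) and np.all(finite > 0):
            emg_threshold = float(np.exp(_otsu_split(np.log(finite))))
        else:
            emg_threshold = float(_otsu_split(finite)) if len(finite) else 0.0
    if activity_threshold is None:
        activity_threshold = _noise_floor(act[~np.isnan(act)]) if len(act) else 0.0

    labels = []
    n_unscorable = 0
    for e, a, r in zip(emg, act, ratio):
        if np.isnan(e):
            labels.append("WAKE")
            n_unscorable += 1
        elif e > emg_threshold and a > activity_threshold:
            labels.append("ACTIVE_WAKE")
        elif e > emg_threshold:
            labels.append("WAKE")
        elif not np.isnan(r) and r > ratio_threshold:
            labels.append("PARADOXICAL")
        else:
            labels.append("SWS")

    if smooth and len(labels) >= 3:
        smoothed = labels[:]
        for k in range(1, len(labels) - 1):
            window = labels[k - 1 : k + 2]
            counts = {s: window.count(s) for s in set(window)}
            best = max(counts.values())
            if best >= 2:
                smoothed[k] = next(s for s in window if counts[s] == best)
        labels = smoothed

    return Hypnogram(
        epoch_len_s=epoch_len_s,
        labels=labels,
        features=features,
        n_unscorable=n_unscorable,
    )


def state_percentages(hypnogram: Hypnogram) -> StateSummary:
    """Percent of scored time in each state (sums to 100 exactly)."""
    n = len(hypnogram.labels)
    if n == 0:
        raise ValidationError("hypnogram has no epochs")
    counts = {s: hypnogram.labels.count(s) for s in _STATES}
    return StateSummary(
        percent_active_wake=100.0 * counts["ACTIVE_WAKE"] / n,
        percent_wake=100.0 * counts["WAKE"] / n,
        percent_sws=100.0 * counts["SWS"] / n,
        percent_paradoxical=100.0 * counts["PARADOXICAL"] / n,
    )
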