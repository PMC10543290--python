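"""Domain containers and on-disk formats for the EEG/MEA phenotyping pipeline.

Continuous biopotential recordings travel as EDF (one signal per channel,
amplitudes in microvolts); MEA spike rasters travel as a two-column CSV
(``electrode_id,spike_time_s``) with a JSON metadata sidecar; hypnograms and
metric tables are plain CSV.  All times are seconds from recording start and
all indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .errors import FormatError, ValidationError

__all__ = [
    "SignalRecording",
    "SpikeRaster",
    "read_edf",
    "write_edf",
    "read_raster",
    "write_raster",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "write_metrics_csv",
]

# Microvolt conversion factors by physical-dimension label (case-insensitive).
_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0, "a.u.": 1.0}


@dataclass
class SignalRecording:
    """Multi-channel telemetry recording: EEG + EMG biopotentials and activity.

    EEG and EMG are in microvolts and share one sampling rate (500 Hz for the
    wireless telemetry this pipeline targets); the locomotor-activity trace is
    in arbitrary units at its own rate (200 Hz by default).
    """

    eeg: np.ndarray
    emg: np.ndarray
    activity: np.ndarray
    sampling_rate_hz: float = 500.0
    activity_sampling_rate_hz: float = 200.0
    duration_s: float = 0.0
    subject_id: str = ""
    group_label: str = ""
    light_phase_onsets: list[float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.duration_s == 0.0 and len(self.eeg):
            self.duration_s = len(self.eeg) / self.sampling_rate_hz
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0 or self.activity_sampling_rate_hz <= 0:
            raise ValidationError("sampling rates must be strictly positive")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if len(self.eeg) != len(self.emg):
            raise ValidationError("EEG and EMG must share a sampling rate and length")
        for name, series, rate in (
            ("eeg", self.eeg, self.sampling_rate_hz),
            ("emg", self.emg, self.sampling_rate_hz),
            ("activity", self.activity, self.activity_sampling_rate_hz),
        ):
            expected = self.duration_s * rate
            if abs(len(series) - expected) > 1.0:
                raise ValidationError(
                    f"{name} has {len(series)} samples; expected "
                    f"{expected:g} for {self.duration_s} s at {rate} Hz"
                )


@dataclass
class SpikeRaster:
    """Spike-event list from a high-density microelectrode array.

    Events are stored as parallel arrays in canonical (time, electrode) order.
    The full array has 26,400 electrodes; a recording typically carries events
    from the active subset only.
    """

    electrode_ids: np.ndarray
    spike_times_s: np.ndarray
    n_electrodes: int = 26_400
    duration_s: float = 300.0
    array_shape: tuple[int, int] = (120, 220)

    def __post_init__(self):
        self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.int64)
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        order = np.lexsort((self.electrode_ids, self.spike_times_s))
        self.electrode_ids = self.electrode_ids[order]
        self.spike_times_s = self.spike_times_s[order]
        self.validate()

    def validate(self) -> None:
        if len(self.electrode_ids) != len(self.spike_times_s):
            raise ValidationError("electrode_ids and spike_times_s lengths differ")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if len(self.spike_times_s):
            bad = np.flatnonzero(
                (self.spike_times_s < 0) | (self.spike_times_s >= self.duration_s)
            )
            if len(bad):
                raise ValidationError(
                    f"event at row {bad[0]} has time "
                    f"{self.spike_times_s[bad[0]]:g} outside [0, {self.duration_s} s)"
                )
            if self.electrode_ids.min() < 0 or self.electrode_ids.max() >= self.n_electrodes:
                raise ValidationError("electrode_id outside [0, n_electrodes)")

    @property
    def n_events(self) -> int:
        return len(self.spike_times_s)

    def events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"electrode_id": self.electrode_ids, "spike_time_s": self.spike_times_s}
        )


# ---------------------------------------------------------------------------
# EDF

def _find_channel(edf: _edf.EdfFile, prefix: str) -> _edf.EdfSignal | None:
    for sig in edf.signals:
        if sig.label.lower().startswith(prefix.lower()):
            return sig
    return None


def _to_uv(sig: _edf.EdfSignal) -> np.ndarray:
    factor = _UNIT_TO_UV.get(sig.physical_dim.strip().lower(), 1.0)
    return sig.data * factor


def read_edf(path) -> SignalRecording:
    """Read an EDF file with EEG, EMG and (optionally) ACT channels.

    Channel matching is a case-insensitive prefix match on the signal label.
    A missing ACT channel yields an all-zero activity trace, flagged with
    ``metadata["activity_missing"] = True``.
    """
    path = Path(path)
    try:
        edf = _edf.read_edf_file(path)
    except FormatError:
        raise
    except OSError:
        raise
    except Exception as exc:  # malformed numeric fields etc.
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc

    eeg = _find_channel(edf, "EEG")
    emg = _find_channel(edf, "EMG")
    if eeg is None:
        raise FormatError("EEG channel not found")
    if emg is None:
        raise FormatError("EMG channel not found")
    act = _find_channel(edf, "ACT")

    duration = edf.n_records * edf.record_duration_s
    metadata = {"source": str(path)}
    if act is None:
        n_act = int(round(duration * 200.0))
        activity = np.zeros(n_act)
        act_rate = 200.0
        metadata["activity_missing"] = True
    else:
        activity = act.data
        act_rate = act.sampling_rate_hz

    return SignalRecording(
        eeg=_to_uv(eeg),
        emg=_to_uv(emg),
        activity=activity,
        sampling_rate_hz=eeg.sampling_rate_hz,
        activity_sampling_rate_hz=act_rate,
        duration_s=duration,
        subject_id=edf.patient_id if edf.patient_id != "X" else "",
        group_label=edf.recording_id if edf.recording_id != "X" else "",
        metadata=metadata,
    )


def write_edf(recording: SignalRecording, path) -> Path:
    """Write a recording as EDF with one signal per channel.

    Physical ranges are chosen symmetric around zero, just covering the data,
    so amplitude error is bounded by one 16-bit quantization step.
    """
    recording.validate()
    path = Path(path)
    signals = [
        _edf.EdfSignal("EEG", "uV", recording.sampling_rate_hz, recording.eeg),
        _edf.EdfSignal("EMG", "uV", recording.sampling_rate_hz, recording.emg),
        _edf.EdfSignal(
            "ACT", "a.u.", recording.activity_sampling_rate_hz, recording.activity
        ),
    ]
    edf = _edf.EdfFile(
        signals=signals,
        record_duration_s=1.0,
        patient_id=recording.subject_id or "X",
        recording_id=recording.group_label or "X",
    )
    _edf.write_edf_file(path, edf)
    return path


# ---------------------------------------------------------------------------
# Spike rasters: CSV + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_raster(raster: SpikeRaster, path) -> Path:
    raster.validate()
    path = Path(path)
    raster.events().to_csv(path, index=False)
    meta = {
        "n_electrodes": int(raster.n_electrodes),
        "duration_s": float(raster.duration_s),
        "array_shape": list(raster.array_shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    for col in ("electrode_id", "spike_time_s"):
        if col not in df.columns:
            raise FormatError(f"raster CSV missing column {col!r}")
    return SpikeRaster(
        electrode_ids=df["electrode_id"].to_numpy(),
        spike_times_s=df["spike_time_s"].to_numpy(),
        n_electrodes=int(meta["n_electrodes"]),
        duration_s=float(meta["duration_s"]),
        array_shape=tuple(meta.get("array_shape", (120, 220))),
    )


# ---------------------------------------------------------------------------
# Hypnograms and metric tables

def write_hypnogram_csv(hypnogram, path) -> Path:
    """Write one row per scored epoch: start_s, state."""
    path = Path(path)
    starts = np.arange(len(hypnogram.labels)) * hypnogram.epoch_len_s
    pd.DataFrame({"start_s": starts, "state": list(hypnogram.labels)}).to_csv(
        path, index=False
    )
    return path


def read_hypnogram_csv(path, epoch_len_s: float | None = None):
    """Read a hypnogram CSV back into a Hypnogram (labels + epoch length)."""
    from .sleep_staging import Hypnogram

    df = pd.read_csv(path)
    if epoch_len_s is None:
        if len(df) >= 2:
            epoch_len_s = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
        else:
            warnings.warn("single-epoch hypnogram: assuming 10 s epochs")
            epoch_len_s = 10.0
    return Hypnogram(epoch_len_s=epoch_len_s, labels=list(df["state"]))


def write_metrics_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
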