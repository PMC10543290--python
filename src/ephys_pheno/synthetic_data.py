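"""Synthetic EEG/EMG/activity recordings and MEA spike rasters with ground truth.

The EEG generator draws a per-epoch vigilance-state sequence from a 4-state
Markov chain (active wake, quiet wake, slow-wave sleep, paradoxical sleep)
and mixes, per state, three unit-variance noise components — band-limited
delta (0.5-4 Hz), band-limited theta (5-9 Hz) and 1/f broadband — scaled by
per-state amplitudes, so band power scales exactly with amplitude squared.
EMG is white noise at a per-state RMS (high in wake, atonia in paradoxical
sleep); the activity trace is a per-state locomotion level plus sensor noise.
Epileptiform spike trains are clusters of biphasic transients superimposed on
the EEG at Poisson-placed onsets.

The MEA generator emits homogeneous Poisson background firing on a subset of
active electrodes plus synchronized network bursts: during a burst window,
participating electrodes multiply their rate by a fixed factor.

Both generators return the recording together with a :class:`GroundTruth`
(true hypnogram, spike-train intervals, burst windows) so detection and
scoring stages can be validated without animal or culture data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io_formats import SignalRecording, SpikeRaster

__all__ = [
    "STATES",
    "EegSimConfig",
    "MeaSimConfig",
    "GroundTruth",
    "simulate_eeg",
    "simulate_raster",
    "genotype_preset",
    "stationary_distribution",
]

STATES = ("ACTIVE_WAKE", "WAKE", "SWS", "PARADOXICAL")

# Default per-state mixing amplitudes, µV: (delta, theta, broadband).
_DEFAULT_BAND_AMPS = {
    "ACTIVE_WAKE": (20.0, 35.0, 30.0),
    "WAKE": (25.0, 25.0, 30.0),
    "SWS": (60.0, 15.0, 25.0),
    "PARADOXICAL": (10.0, 45.0, 20.0),
}
# Muscle tone per state, µV RMS: high when moving, atonia in paradoxical sleep.
_DEFAULT_EMG_RMS = {
    "ACTIVE_WAKE": 40.0,
    "WAKE": 25.0,
    "SWS": 5.0,
    "PARADOXICAL": 2.0,
}
# Locomotor-activity level per state (arbitrary units of the telemetry sensor).
_DEFAULT_ACTIVITY = {
    "ACTIVE_WAKE": 5.0,
    "WAKE": 0.0,
    "SWS": 0.0,
    "PARADOXICAL": 0.0,
}


def _sticky_matrix(pi: np.ndarray, stay: float = 0.7) -> np.ndarray:
    """Row-stochastic matrix with stationary distribution ``pi``.

    Each row is ``stay``·(self) + (1-stay)·pi, which keeps dwell times of a
    few epochs while making the stationary distribution exactly ``pi``.
    """
    pi = np.asarray(pi, dtype=float)
    return stay * np.eye(len(pi)) + (1 - stay) * np.tile(pi, (len(pi), 1))


_DEFAULT_TRANSITIONS = _sticky_matrix([0.18, 0.22, 0.46, 0.14])


@dataclass
class EegSimConfig:
    """Parameters of the synthetic EEG/EMG/activity recording."""

    duration_s: float = 600.0
    epoch_len_s: float = 10.0
    state_transition_matrix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_TRANSITIONS.copy()
    )
    band_amps: dict = field(default_factory=lambda: dict(_DEFAULT_BAND_AMPS))
    emg_rms: dict = field(default_factory=lambda: dict(_DEFAULT_EMG_RMS))
    activity_level: dict = field(default_factory=lambda: dict(_DEFAULT_ACTIVITY))
    activity_noise_sd: float = 0.05
    spike_train_rate_per_hour: float = 0.0
    spikes_per_train_range: tuple[int, int] = (3, 6)
    intra_train_gap_s: float = 0.2
    spike_amplitude_uv: float = 450.0
    n_spike_trains: int | None = None  # exact count override (else Poisson)
    sampling_rate_hz: float = 500.0
    activity_sampling_rate_hz: float = 200.0
    rng_seed: int = 0

    def validate(self) -> None:
        P = np.asarray(self.state_transition_matrix, dtype=float)
        if P.shape != (4, 4):
            raise ValidationError("state_transition_matrix must be 4x4")
        if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("state_transition_matrix rows must sum to 1")
        if self.epoch_len_s <= 0 or self.duration_s <= 0:
            raise ValidationError("duration_s and epoch_len_s must be positive")
        n_epochs = self.duration_s / self.epoch_len_s
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValidationError("epoch_len_s must divide duration_s")
        for st in STATES:
            if any(a < 0 for a in self.band_amps[st]):
                raise ValidationError("band amplitudes must be >= 0")
            if self.emg_rms[st] < 0:
                raise ValidationError("emg_rms must be >= 0")
        if self.spike_train_rate_per_hour < 0 or self.spike_amplitude_uv < 0:
            raise ValidationError("spike-train parameters must be >= 0")


@dataclass
class MeaSimConfig:
    """Parameters of the synthetic MEA spike raster."""

    n_electrodes: int = 26_400
    n_active_electrodes: int = 1024
    duration_s: float = 300.0
    baseline_rate_hz: float = 1.0
    burst_rate_per_min: float = 0.0
    burst_duration_s: float = 0.3
    within_burst_rate_multiplier: float = 15.0
    electrode_participation_prob: float = 0.6
    n_bursts: int | None = None  # exact count override (else Poisson)
    array_shape: tuple[int, int] = (120, 220)
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.electrode_participation_prob <= 1:
            raise ValidationError("electrode_participation_prob must be in [0,1]")
        if self.baseline_rate_hz < 0 or self.burst_rate_per_min < 0:
            raise ValidationError("rates must be >= 0")
        if self.within_burst_rate_multiplier < 0:
            raise ValidationError("within_burst_rate_multiplier must be >= 0")
        if self.n_active_electrodes > self.n_electrodes:
            raise ValidationError("n_active_electrodes must be <= n_electrodes")
        if self.burst_duration_s <= 0 or self.duration_s <= 0:
            raise ValidationError("durations must be positive")
        if self.burst_duration_s > self.duration_s:
            raise ValidationError("burst duration exceeds recording duration")


@dataclass
class GroundTruth:
    """Generator-side truth used to validate detection and scoring stages."""

    hypnogram: list[str] = field(default_factory=list)
    spike_train_times: list[tuple[float, float, int]] = field(default_factory=list)
    burst_times: list[tuple[float, float, float, int]] = field(default_factory=list)
    active_electrodes: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "hypnogram": list(self.hypnogram),
            "spike_train_times": [list(t) for t in self.spike_train_times],
            "burst_times": [list(t) for t in self.burst_times],
            "active_electrodes": (
                self.active_electrodes.tolist()
                if self.active_electrodes is not None
                else None
            ),
        }


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _unit_bandpass_noise(rng, n, fs, lo, hi) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _unit_pink_noise(rng, n, fs, lo=0.5, hi=100.0) -> np.ndarray:
    """Unit-variance 1/f (power exponent 1) noise limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= lo) & (freqs <= hi)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _biphasic_transient(fs: float, width_s: float = 0.04) -> np.ndarray:
    """One positive and one negative half-sine lobe, peak amplitude 1."""
    n = max(int(round(width_s * fs)), 4)
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t)


def _place_intervals(rng, n, duration, item_len, guard, max_tries=10_000):
    """Draw n non-overlapping onsets in [guard, duration-item_len-guard]."""
    hi = duration - item_len - guard
    if hi <= guard:
        raise ValidationError("intervals do not fit within the recording duration")
    onsets: list[float] = []
    tries = 0
    min_sep = item_len + guard
    while len(onsets) < n:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"cannot place {n} non-overlapping intervals of {item_len:g} s "
                f"in {duration:g} s"
            )
        cand = rng.uniform(guard, hi)
        if all(abs(cand - o) >= min_sep for o in onsets):
            onsets.append(cand)
    return sorted(onsets)


def simulate_eeg(
    config: EegSimConfig,
    subject_id: str = "",
    group_label: str = "",
) -> tuple[SignalRecording, GroundTruth]:
    """Generate one telemetry recording plus its ground truth.

    Deterministic for a fixed ``config.rng_seed``: the same config produces a
    bit-identical recording.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    fs = config.sampling_rate_hz
    fs_act = config.activity_sampling_rate_hz
    n = int(round(config.duration_s * fs))
    n_act = int(round(config.duration_s * fs_act))
    n_epochs = int(round(config.duration_s / config.epoch_len_s))
    spe = int(round(config.epoch_len_s * fs))  # samples per epoch (EEG/EMG)
    spe_act = int(round(config.epoch_len_s * fs_act))

    # --- hypnogram from the Markov chain (started at stationarity)
    P = np.asarray(config.state_transition_matrix, dtype=float)
    pi = stationary_distribution(P)
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(4, p=pi)
    for k in range(1, n_epochs):
        states[k] = rng.choice(4, p=P[states[k - 1]])
    labels = [STATES[s] for s in states]

    # --- continuous unit-variance components, scaled by per-epoch amplitudes
    delta = _unit_bandpass_noise(rng, n, fs, 0.5, 4.0)
    theta = _unit_bandpass_noise(rng, n, fs, 5.0, 9.0)
    pink = _unit_pink_noise(rng, n, fs)

    amps = np.array([config.band_amps[STATES[s]] for s in states])  # (n_epochs, 3)
    env = np.repeat(amps, spe, axis=0)[:n]
    eeg = env[:, 0] * delta + env[:, 1] * theta + env[:, 2] * pink

    emg_env = np.repeat(
        np.array([config.emg_rms[STATES[s]] for s in states]), spe
    )[:n]
    emg = emg_env * rng.standard_normal(n)

    act_env = np.repeat(
        np.array([config.activity_level[STATES[s]] for s in states]), spe_act
    )[:n_act]
    activity = act_env + config.activity_noise_sd * rng.standard_normal(n_act)

    # --- epileptiform spike trains
    truth_trains: list[tuple[float, float, int]] = []
    if config.n_spike_trains is not None:
        n_trains = int(config.n_spike_trains)
    else:
        n_trains = int(
            rng.poisson(config.spike_train_rate_per_hour * config.duration_s / 3600.0)
        )
    if n_trains > 0 and config.spike_amplitude_uv > 0:
        lo_k, hi_k = config.spikes_per_train_range
        max_len = (hi_k - 1) * config.intra_train_gap_s + 0.1
        onsets = _place_intervals(rng, n_trains, config.duration_s, max_len, guard=5.0)
        wave = _biphasic_transient(fs) * config.spike_amplitude_uv
        for onset in onsets:
            k = int(rng.integers(lo_k, hi_k + 1))
            spike_times = onset + np.arange(k) * config.intra_train_gap_s
            for t in spike_times:
                i0 = int(round(t * fs))
                i1 = min(i0 + len(wave), n)
                eeg[i0:i1] += wave[: i1 - i0]
            truth_trains.append((float(spike_times[0]), float(spike_times[-1]), k))

    recording = SignalRecording(
        eeg=eeg,
        emg=emg,
        activity=activity,
        sampling_rate_hz=fs,
        activity_sampling_rate_hz=fs_act,
        duration_s=config.duration_s,
        subject_id=subject_id,
        group_label=group_label,
        metadata={"rng_seed": config.rng_seed},
    )
    truth = GroundTruth(hypnogram=labels, spike_train_times=truth_trains)
    return recording, truth


def simulate_raster(config: MeaSimConfig) -> tuple[SpikeRaster, GroundTruth]:
    """Generate one MEA raster (Poisson background + planted network bursts)."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    T = config.duration_s

    active = np.sort(
        rng.choice(config.n_electrodes, size=config.n_active_electrodes, replace=False)
    )

    # background: homogeneous Poisson per active electrode
    counts = rng.poisson(config.baseline_rate_hz * T, size=len(active))
    ids = np.repeat(active, counts)
    times = rng.uniform(0.0, T, size=counts.sum())

    # bursts
    if config.n_bursts is not None:
        n_bursts = int(config.n_bursts)
    else:
        n_bursts = int(rng.poisson(config.burst_rate_per_min * T / 60.0))
    truth_bursts: list[tuple[float, float, float, int]] = []
    extra_ids, extra_times = [], []
    if n_bursts > 0:
        onsets = _place_intervals(
            rng, n_bursts, T, config.burst_duration_s, guard=2 * config.burst_duration_s
        )
        extra_rate = config.baseline_rate_hz * (config.within_burst_rate_multiplier - 1)
        for onset in onsets:
            offset = onset + config.burst_duration_s
            participating = active[
                rng.random(len(active)) < config.electrode_participation_prob
            ]
            k = rng.poisson(
                max(extra_rate, 0.0) * config.burst_duration_s, size=len(participating)
            )
            extra_ids.append(np.repeat(participating, k))
            extra_times.append(rng.uniform(onset, offset, size=k.sum()))
            truth_bursts.append((onset, onset + config.burst_duration_s / 2, offset, 0))

    if extra_ids:
        ids = np.concatenate([ids] + extra_ids)
        times = np.concatenate([times] + extra_times)

    raster = SpikeRaster(
        electrode_ids=ids,
        spike_times_s=times,
        n_electrodes=config.n_electrodes,
        duration_s=T,
        array_shape=config.array_shape,
    )

    # fill per-burst pooled spike counts from the assembled raster
    filled = []
    for onset, peak, offset, _ in truth_bursts:
        in_win = np.count_nonzero(
            (raster.spike_times_s >= onset) & (raster.spike_times_s <= offset)
        )
        filled.append((onset, peak, offset, int(in_win)))

    truth = GroundTruth(burst_times=filled, active_electrodes=active)
    return raster, truth


# ---------------------------------------------------------------------------
# Genotype presets

def genotype_preset(name: str) -> tuple[EegSimConfig, MeaSimConfig]:
    """Return (EEG config, MEA config) styled after a wild-type or mutant animal.

    ``"HET"`` (heterozygous mutant) differs from ``"WT"`` by elevated delta and
    theta amplitudes, more frequent and longer epileptiform spike trains, a
    sleep architecture shifted toward active wake and away from slow-wave
    sleep, and on the array more frequent network bursts carrying fewer spikes
    each (hence shorter inter-burst intervals).  Magnitudes are illustrative
    defaults chosen to be clearly resolvable by the analysis stages; all are
    plain dataclass fields and can be overridden.
    """
    if name == "WT":
        eeg = EegSimConfig(
            state_transition_matrix=_sticky_matrix([0.18, 0.22, 0.46, 0.14]),
            spike_train_rate_per_hour=6.0,
            spikes_per_train_range=(3, 6),
        )
        mea = MeaSimConfig(
            n_active_electrodes=256,
            baseline_rate_hz=1.0,
            burst_rate_per_min=3.0,
            burst_duration_s=0.3,
            within_burst_rate_multiplier=15.0,
            electrode_participation_prob=0.6,
        )
        return eeg, mea
    if name == "HET":
        het_amps = {
            st: (1.25 * d, 1.10 * t, b)
            for st, (d, t, b) in _DEFAULT_BAND_AMPS.items()
        }
        eeg = EegSimConfig(
            state_transition_matrix=_sticky_matrix([0.28, 0.18, 0.41, 0.13]),
            band_amps=het_amps,
            spike_train_rate_per_hour=30.0,
            spikes_per_train_range=(4, 10),
        )
        mea = MeaSimConfig(
            n_active_electrodes=256,
            baseline_rate_hz=1.0,
            burst_rate_per_min=6.0,
            burst_duration_s=0.25,
            within_burst_rate_multiplier=10.0,
            electrode_participation_prob=0.5,
        )
        return eeg, mea
    raise ValidationError(f"unknown genotype preset {name!r} (expected 'WT' or 'HET')")
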