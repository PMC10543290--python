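import numpy as np
import pytest

from ephys_pheno.io_formats import SignalRecording
from ephys_pheno.synthetic_data import (
    EegSimConfig,
    MeaSimConfig,
    genotype_preset,
    simulate_eeg,
    simulate_raster,
)


@pytest.fixture(scope="session")
def wt_recording():
    """One wild-type preset recording (600 s) with its ground truth."""
    cfg, _ = genotype_preset("WT")
    cfg.duration_s = 600.0
    cfg.rng_seed = 11
    return simulate_eeg(cfg, subject_id="wt11", group_label="WT")


@pytest.fixture(scope="session")
def burst_raster():
    """A 300 s raster with 12 planted network bursts over Poisson background."""
    cfg = MeaSimConfig(
        n_active_electrodes=128,
        baseline_rate_hz=1.0,
        n_bursts=12,
        burst_duration_s=0.3,
        within_burst_rate_multiplier=15.0,
        electrode_participation_prob=0.6,
        rng_seed=7,
    )
    return simulate_raster(cfg)


@pytest.fixture()
def noise_recording():
    """White-noise biopotentials, handy for handcrafted event injection."""
    rng = np.random.default_rng(42)
    fs, dur = 500.0, 20.0
    n = int(fs * dur)
    return SignalRecording(
        eeg=10.0 * rng.standard_normal(n),
        emg=5.0 * rng.standard_normal(n),
        activity=np.zeros(int(200 * dur)),
        duration_s=dur,
    )


def make_sine_recording(freq_hz=8.0, amplitude=50.0, duration_s=60.0, fs=500.0):
    t = np.arange(int(duration_s * fs)) / fs
    n_act = int(200 * duration_s)
    return SignalRecording(
        eeg=amplitude * np.sin(2 * np.pi * freq_hz * t),
        emg=np.zeros_like(t),
        activity=np.zeros(n_act),
        duration_s=duration_s,
    )
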