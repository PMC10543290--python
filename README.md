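# ephys-pheno

Neurophysiological phenotyping for mutant-mouse studies: EEG band-power
analysis, epileptiform spike-train detection, four-state sleep scoring, and
high-density microelectrode-array (HD-MEA) network-burst quantification,
with the group-statistics layer used in such studies (2-SD inclusion
filter, two-tailed Student's t, two-way ANOVA with Sidak/Holm-Sidak/
Bonferroni-Dunn post hocs).

The package targets the common telemetry + culture workflow: wireless
EEG/EMG implants sampled at 500 Hz (plus a 200 Hz activity trace) in freely
moving animals, and 26,400-electrode arrays recording primary neuronal
cultures across days in vitro.  Because such studies rarely ship raw data,
a synthetic generator produces recordings and rasters with genotype-styled
statistics and ground truth (true hypnogram, planted spike trains, planted
bursts), so every detection and scoring stage is verifiable end to end.

## What it computes

- **Spectra** — Welch PSD (Hann, 2 s windows, 50% overlap, µV²/Hz) and
  absolute band power by trapezoidal integration; default bands delta
  0.5–4 Hz, theta 5–9 Hz, alpha 9–12, beta 12–30, gamma 30–100.
- **Spike trains** — robust amplitude thresholding (MAD-scaled, 5 SD) on
  1–70 Hz band-passed EEG, refractory suppression, single-linkage grouping
  (gap ≤ 2 s, ≥ 3 spikes); count, rate, and duration summaries.
- **Sleep** — per-epoch features (delta/theta power, theta/delta ratio, EMG
  RMS, activity) scored by ordered rules into active wake / wake / slow-wave
  sleep / paradoxical sleep; state percentages per recording.
- **MEA** — activity scan, top-1024 electrode selection, Gaussian-smoothed
  population rate (σ = 50 ms), network-burst detection with robust
  thresholding; spikes/burst, inter-burst interval (peak-to-peak), burst
  count and duration per chip across days in vitro.
- **Statistics** — single-pass 2-SD inclusion filter, pooled-variance t,
  between-subject or mixed two-way ANOVA, post hoc multiplicity control.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate one wild-type and one mutant-style recording, then compare:

```sh
ephys-pheno simulate-eeg --preset WT  --duration 600 --seed 1 --out wt.edf
ephys-pheno simulate-eeg --preset HET --duration 600 --seed 1 --out het.edf
ephys-pheno spikes --edf het.edf --out het_trains.csv
ephys-pheno sleep  --edf het.edf --out het_hyp.csv
```

The `spikes` command prints the train summary for the mutant-style
recording:

```json
{"train_count": 3, "trains_per_hour": 18.0, "mean_duration_s": 1.133, "total_spikes": 20}
```

three detected epileptiform spike trains in 10 minutes (18/h), averaging
1.1 s and 6–7 spikes each — against a wild-type preset rate of 6/h.  The
`sleep` command prints the state percentages:

```json
{"percent_active_wake": 16.67, "percent_wake": 23.33, "percent_sws": 48.33, "percent_paradoxical": 11.67}
```

i.e. this mutant-style animal spent 48% of scored epochs in slow-wave
sleep and 17% in active wake.  Full cohort pipelines with group statistics:

```sh
ephys-pheno run-eeg --outdir eeg_run --seed 1   # n=8/genotype: PSD, spikes, sleep, t-tests
ephys-pheno run-mea --outdir mea_run --seed 1   # 6 chips x 5 DIVs/genotype: bursts, ANOVA
```

`eeg_run/comparisons.csv` then holds one row per metric (band powers,
train counts, state percentages) with group means, t, df, p and direction;
`mea_run/stats.csv` holds the genotype × DIV ANOVA effects and per-DIV
Sidak-adjusted comparisons.

The same commands accept real data: `psd`/`spikes`/`sleep` read EDF files
with EEG, EMG and optional ACT channels; `mea` reads `electrode_id,
spike_time_s` CSVs with a JSON metadata sidecar.

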