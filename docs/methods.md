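# Methods

`ephys-pheno` quantifies neurophysiological phenotypes of mutant-mouse
models on two recording modalities: wireless EEG/EMG telemetry from freely
moving animals, and extracellular spike rasters from primary neuronal
cultures on high-density microelectrode arrays (HD-MEA).  Every analysis
stage is validated against a synthetic-data generator that carries its own
ground truth, so the pipeline's detection and scoring behaviour can be
measured without animal or culture data.

## Signal model and synthetic generator

**EEG/EMG/activity.**  A recording is a triple of series: EEG and EMG at
500 Hz (µV, band-limited 0.1–100 Hz by the acquisition hardware this format
targets) and a locomotor-activity trace at 200 Hz (arbitrary units).  The
generator draws a per-epoch vigilance state sequence from a 4-state Markov
chain over {active wake, quiet wake, slow-wave sleep (SWS), paradoxical
sleep}; the default transition matrix is "sticky" —
`P = 0.7·I + 0.3·1πᵀ` — which gives dwell times of a few epochs and makes
the stationary distribution exactly the design occupancy π.  Epochs are
10 s by default (configurable); state is constant within an epoch, matching
the epoch-granular scorer downstream.

Within an epoch the EEG is a mixture of three unit-variance components
scaled by per-state amplitudes: band-limited delta noise (0.5–4 Hz, 4th-order
Butterworth, forward–backward filtered), band-limited theta noise (5–9 Hz),
and 1/f broadband noise (power exponent 1, limited to 0.5–100 Hz, shaped in
the frequency domain).  Because each component has unit variance, band power
scales exactly with amplitude squared, which the tests exploit.  Default
per-state amplitudes (delta, theta, broadband, µV) are:

| state            | delta | theta | broadband | EMG RMS | activity |
|------------------|------:|------:|----------:|--------:|---------:|
| active wake      |  20   |  35   |   30      |  40     |  5.0     |
| wake (quiet)     |  25   |  25   |   30      |  25     |  0.0     |
| SWS              |  60   |  15   |   25      |   5     |  0.0     |
| paradoxical      |  10   |  45   |   20      |   2     |  0.0     |

These encode the standard physiology: delta-dominant SWS, theta-dominant
paradoxical (REM-like) sleep with muscle atonia, high muscle tone and
locomotion in active wake.  EMG is white noise at the state's RMS; activity
is the state's level plus sensor noise (SD 0.05 a.u.).

**Epileptiform spike trains** are clusters of biphasic transients (one
positive and one negative half-sine lobe, 40 ms total — a simple idealization
of a sharp interictal discharge) with peak amplitude 450 µV by default,
intra-train spacing 0.2 s, 3–6 spikes per train, superimposed on the EEG.
Train onsets are Poisson at a configurable hourly rate and placed with a 5 s
guard so trains never overlap; an exact-count override (`n_spike_trains`)
exists for planting a known number.  Onset, offset and spike count of every
train are recorded as ground truth.

**MEA rasters.**  Active electrodes (default 1024 of 26,400) fire as
homogeneous Poisson processes at a baseline rate (1 Hz default).  Network
bursts occur at a configurable per-minute rate; during a burst window
(0.3 s default) each active electrode participates with probability 0.6 and
multiplies its rate by 15.  Burst windows are placed non-overlapping with a
guard of two burst durations, which biases inter-burst intervals upward by
a few percent relative to a pure Poisson process — negligible at the default
rates.

**Genotype presets.**  `genotype_preset("WT"/"HET")` returns paired configs
in which the heterozygous-mutant style differs from wild type by: delta
amplitudes ×1.25 and theta ×1.10 in every state; spike-train rate 30/h vs
6/h with longer trains (4–10 vs 3–6 spikes); sleep architecture shifted
toward active wake (stationary occupancy 0.28 vs 0.18) and away from SWS
(0.41 vs 0.46); and on the array, more frequent bursts (6/min vs 3/min)
carrying fewer spikes each (participation 0.5 vs 0.6, multiplier 10 vs 15,
duration 0.25 s vs 0.3 s).  The magnitudes are illustrative — chosen once so
that every contrast is clearly resolvable by the analysis stages at the
cohort sizes used — not fitted to any dataset; only the directions are
meaningful.

What the generator deliberately does not model: mid-epoch state
transitions, circadian (light/dark) modulation, movement and chewing
artifacts beyond what the artifact-rejection rule needs, electrode drift,
spike-waveform variability, and bursts with internal structure.  Passing
recovery tests on this generator therefore demonstrates correctness of the
analysis logic under the stated signal model, not performance on real
telemetry, where scorer agreement is limited by boundary epochs and
artifacts.

## Spectral analysis

PSDs are Welch estimates: Hann-tapered segments, 2 s default window (0.5 Hz
resolution, enough to resolve the 0.5 Hz lower delta edge), 50% overlap,
density scaling in µV²/Hz so the integral over frequency recovers the
signal variance.  Band powers are trapezoidal integrals of the PSD over the
band, with interpolated edge points when an edge falls between grid
frequencies.  Default bands: delta 0.5–4 Hz, theta 5–9 Hz (the 4–5 Hz gap is
kept on purpose, as is conventional in this assay), alpha 9–12, beta 12–30,
gamma 30–100.  Absolute power is primary; relative power is a derived
column.

One numerical caveat drives a choice in the validation harness: a pure tone
whose Hann main lobe touches the integration band's edge bins loses the
half-weight the trapezoid assigns to edges (a tone at 8 Hz integrated over
7.5–8.5 Hz at 0.5 Hz resolution recovers 5/6 of A²/2).  The sinusoid
closed-form check therefore uses 4 s windows (0.25 Hz resolution), placing
the main lobe strictly inside the band, where the closed form is recovered
to machine precision.

Artifact handling: non-overlapping windows whose RMS exceeds 6× the median
window RMS are excluded and Welch averaging is performed over the remaining
clean runs, weighted by segment count.  The same weighted averaging makes
the pooled spectrum of equal-length chunks equal the chunk mean
(`longitudinal_psd`), exactly so at zero overlap.

## Spike-train detection

EEG is band-passed to 1–70 Hz; the baseline scale is the robust SD
(1.4826 × median absolute deviation), so the spikes being detected do not
inflate their own threshold.  Local extrema of the absolute filtered signal
above `threshold_sd` (default 5) baseline units become events; events within
a refractory window (50 ms) of a larger event are suppressed, collapsing the
two lobes of one biphasic transient into one detection.  Trains are
single-linkage clusters in time (gap ≤ 2 s), discarded below 3 spikes.  The
defaults are declared, CLI-exposed operating points, not values taken from
any external protocol.  Train duration is last-minus-first spike time;
spike width (40 ms) is below the timing resolution that matters at this
scale.

## Sleep scoring

Per epoch, the scorer computes delta and theta band power (Welch on the
epoch), their ratio, EMG RMS, and mean activity, then applies ordered rules:
high EMG + movement → active wake; high EMG alone → wake; low EMG with
theta/delta ratio > 1.5 → paradoxical sleep; otherwise SWS.  Unscorable
epochs (missing features) are labeled wake and tallied.

The EMG threshold defaults to an Otsu split (maximum between-class variance)
of the log epoch-EMG-RMS distribution.  This was a deliberate design choice
over a fixed percentile: a percentile threshold couples the cut to the
animal's realized wake/sleep occupancy — with a few hundred epochs the
occupancy fluctuates enough (±10–15 points) to drag a fixed percentile deep
into one of the two EMG clusters, misclassifying 10–20% of epochs, which we
observed directly on 600 s simulations.  The bimodal split tracks the
cluster gap regardless of occupancy while remaining per-recording and
scale-invariant (implant gain cancels).  A percentile rule remains available
(`emg_percentile=`), as does an absolute cutoff (`emg_threshold=`).  The
activity threshold is a noise-floor estimate: median + 5 × scaled-MAD of
epoch mean activity.  Limitation: with a genuinely unimodal EMG distribution
(an animal asleep or awake for the whole recording) the Otsu split falls
inside the single cluster; such recordings need an explicit threshold.

No hypnogram smoothing is applied by default (3-epoch majority vote is
available but off), keeping state percentages unbiased.

## MEA network analysis

The activity scan ranks all electrodes by mean firing rate over the scan
window (30 s); the top n (default 1024, ties broken by ascending electrode
id for reproducibility) are pooled.  The pooled spike train is binned at
dt = 10 ms and convolved with a unit-area Gaussian kernel (σ = 50 ms,
truncated at ±4σ and renormalized on the discrete grid), giving a smoothed
population rate whose integral equals the pooled spike count up to edge
effects (< 0.1%).

Burst detection thresholds the trace at
`max(median + 5 × 1.4826 × MAD, 2 × median)` — robust statistics so that
burst-dominated traces do not raise their own threshold, with the 2×-median
floor guarding near-silent traces.  Supra-threshold candidates are extended
outward to where the trace falls below baseline + 10% of the peak excess;
candidates with peaks closer than 0.2 s merge; overlapping extents after
extension are split at the midpoint between peaks.  Per-burst spike count
pools the selected electrodes over [onset, offset].  The inter-burst
interval is peak-to-peak, and per-chip means of burst count, spikes/burst,
IBI and duration feed the longitudinal (day-in-vitro) table.  All detector
parameters (σ, dt, k, merge gap, boundary fraction) are declared defaults
exposed on the CLI; none is taken from vendor software.

## Group statistics

The 2-SD inclusion filter retains values within two sample SDs of their
group mean, computed once on the full group (single pass, no re-iteration —
re-filtering would cascade at small n).  Groups below n = 3 pass through
unfiltered with a warning.  Between-genotype comparisons use the
pooled-variance two-tailed Student's t (the simulated groups share their
noise model, so equal variances hold by construction).  Factorial designs
use a two-way ANOVA: ordinary OLS with type-II sums of squares for fully
between-subject designs (statsmodels), or a mixed/split-plot ANOVA
(pingouin) when the second factor is repeated within subject, with
complete-case subject dropping.  Post hoc adjustments are Sidak
`1−(1−p)^m`, Bonferroni–Dunn `min(1, mp)`, and step-down Holm–Sidak with
enforced monotonicity.  α = 0.05 throughout.

Calibration of both tests is verified by Monte Carlo on Gaussian nulls:
10,000 replicates each for the t-test and the ANOVA group effect, a size
chosen so the binomial standard error (≈0.0022) resolves the nominal 0.05
level to within ±0.005; at 1,000 replicates the Monte Carlo noise alone
(SD 0.0069) would exceed that resolution.

## Problem sizes and determinism

Validation runs use 600 s recordings for sleep scoring (60 epochs × 20
seeds), 900 s for spike-train recovery (10 seeds × {0, 5, 20} planted
trains), 300 s × 128-active-electrode rasters for burst recovery (20 seeds),
and n = 8 subjects or chips per genotype for direction-of-effect cohorts
(1800 s recordings there, so per-subject occupancy noise does not mask the
~5-point SWS architecture difference).  Simulated cohorts use common random
numbers: subject i of each genotype shares a derived seed, so genotype
contrasts isolate the preset parameter differences.  Every stage is
deterministic given its config seed; pipeline manifests embed the resolved
config, and rerunning a pipeline reproduces its CSVs byte for byte.

## Known limitations

- The EDF codec covers the subset used here (int16 samples, one-second data
  records, no annotations); physical ranges are symmetric per signal.
- The scorer's rule thresholds realize qualitative state definitions; no
  claim is made that they match any laboratory's scoring manual.
- Per-electrode burst statistics and spike sorting are out of scope; bursts
  are population-level events.
- The 2-SD filter is known to be toothless at small n (a single extreme
  value inflates the SD enough to retain itself); this behaviour is
  documented by test rather than "fixed", since it is the assay convention.
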