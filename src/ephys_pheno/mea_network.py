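"""HD-MEA network analysis: activity scan, electrode selection, Gaussian-
smoothed population rate, network-burst detection and burst metrics.

The workflow mirrors standard high-density array practice: a whole-array
activity scan ranks all 26,400 electrodes by mean firing rate; the top 1024
are recorded simultaneously; their pooled spike train, convolved with a
unit-area Gaussian kernel, gives a smoothed population rate whose peaks are
network bursts.  Burst thresholding is robust (median + k x scaled-MAD of
the trace, with a floor of twice the median) so that burst-dominated traces
do not inflate their own threshold.  The inter-burst interval is measured
peak to peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import SpikeRaster

__all__ = [
    "ActivityScanResult",
    "NetworkTrace",
    "NetworkBurst",
    "BurstMetrics",
    "activity_scan",
    "select_top_electrodes",
    "network_trace",
    "detect_bursts",
    "burst_metrics",
    "div_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass
class ActivityScanResult:
    rates_hz: np.ndarray  # one entry per electrode, index = electrode id
    scan_duration_s: float


@dataclass
class NetworkTrace:
    times_s: np.ndarray
    rate_hz: np.ndarray  # smoothed pooled rate, spikes/s
    dt: float
    kernel_sigma_s: float
    n_electrodes_pooled: int


@dataclass(frozen=True)
class NetworkBurst:
    peak_time_s: float
    onset_s: float
    offset_s: float
    n_spikes: int
    peak_rate: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BurstMetrics:
    n_bursts: int
    spikes_per_burst: float
    inter_burst_interval_s: float  # NaN when fewer than 2 bursts
    burst_duration_s: float
    div: int | None = None
    chip_id: str = ""
    group_label: str = ""

    def as_dict(self) -> dict:
        return {
            "chip_id": self.chip_id,
            "group_label": self.group_label,
            "div": self.div,
            "n_bursts": self.n_bursts,
            "spikes_per_burst": self.spikes_per_burst,
            "inter_burst_interval_s": self.inter_burst_interval_s,
            "burst_duration_s": self.burst_duration_s,
        }


def activity_scan(raster: SpikeRaster, scan_duration_s: float = 30.0) -> ActivityScanResult:
    """Mean firing rate per electrode over the first ``scan_duration_s``."""
    if scan_duration_s > raster.duration_s + 1e-9:
        raise ValidationError("scan_duration_s exceeds raster duration")
    in_scan = raster.spike_times_s < scan_duration_s
    counts = np.bincount(
        raster.electrode_ids[in_scan], minlength=raster.n_electrodes
    )
    return ActivityScanResult(
        rates_hz=counts / scan_duration_s, scan_duration_s=scan_duration_s
    )


def select_top_electrodes(scan: ActivityScanResult, n: int = 1024) -> np.ndarray:
    """Ids of the ``n`` highest-rate electrodes (ties broken by ascending id).

    Electrodes with zero rate are never selected; if fewer than ``n`` fire at
    all, the shortfall is logged and all positive-rate electrodes returned.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if n > len(scan.rates_hz):
        raise ValidationError("n exceeds electrode count")
    rates = scan.rates_hz
    positive = np.flatnonzero(rates > 0)
    if len(positive) < n:
        logger.warning(
            "only %d electrodes with nonzero rate (requested %d)", len(positive), n
        )
        chosen = positive
    else:
        # sort by (-rate, id): highest rate first, lower id wins ties
        order = np.lexsort((positive, -rates[positive]))
        chosen = positive[order][:n]
    return np.sort(chosen)


def network_trace(
    raster: SpikeRaster,
    electrodes: np.ndarray,
    kernel_sigma_s: float = 0.05,
    dt: float = 0.01,
) -> NetworkTrace:
    """Pooled spike train of the selected electrodes, Gaussian-smoothed.

    Spikes are binned at ``dt`` and convolved with a discrete Gaussian kernel
    truncated at ±4 sigma and renormalized to unit area, so the integral of
    the trace equals the pooled spike count up to edge effects.
    """
    if kernel_sigma_s <= 0:
        raise ValidationError("kernel_sigma_s must be > 0")
    if dt > kernel_sigma_s / 2 + 1e-12:
        raise ValidationError("dt must be <= kernel_sigma_s / 2")

    n_bins = int(np.ceil(raster.duration_s / dt))
    edges = np.arange(n_bins + 1) * dt
    electrodes = np.asarray(electrodes)
    if len(electrodes) == 0:
        warnings.warn("empty electrode selection: network trace is all zero")
        pooled = np.array([])
    else:
        sel = np.isin(raster.electrode_ids, electrodes)
        pooled = raster.spike_times_s[sel]

    counts, _ = np.histogram(pooled, bins=edges)
    half = int(np.ceil(4 * kernel_sigma_s / dt))
    t_k = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (t_k / kernel_sigma_s) ** 2)
    kernel /= kernel.sum() * dt  # unit area on the discrete grid
    rate = np.convolve(counts, kernel, mode="same")
    centers = edges[:-1] + dt / 2
    return NetworkTrace(
        times_s=centers,
        rate_hz=rate,
        dt=dt,
        kernel_sigma_s=kernel_sigma_s,
        n_electrodes_pooled=len(electrodes),
    )


def detect_bursts(
    trace: NetworkTrace,
    raster: SpikeRaster,
    electrodes: np.ndarray,
    k: float = 5.0,
    boundary_frac: float = 0.10,
    merge_gap_s: float = 0.2,
) -> list[NetworkBurst]:
    """Network bursts as supra-threshold excursions of the smoothed rate.

    threshold = max(median + k * 1.4826 * MAD, 2 * median); candidate regions
    above threshold are extended outward to where the trace falls below
    ``baseline + boundary_frac * (peak - baseline)``, and candidates whose
    peaks are closer than ``merge_gap_s`` merge into one burst.
    """
    rate = trace.rate_hz
    if len(rate) == 0 or not np.any(rate > 0):
        return []
    baseline = float(np.median(rate))
    spread = 1.4826 * float(np.median(np.abs(rate - baseline)))
    threshold = max(baseline + k * spread, 2 * baseline)

    above = rate > threshold
    if not np.any(above):
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(rate) - 1)

    # peak per candidate, then merge candidates with nearby peaks
    cands = []
    for s, e in zip(starts, ends):
        p = s + int(np.argmax(rate[s : e + 1]))
        cands.append([s, e, p])
    merged = [cands[0]]
    for s, e, p in cands[1:]:
        ps = merged[-1][2]
        if (p - ps) * trace.dt < merge_gap_s:
            merged[-1][1] = e
            if rate[p] > rate[merged[-1][2]]:
                merged[-1][2] = p
        else:
            merged.append([s, e, p])

    electrodes = np.asarray(electrodes)
    sel = np.isin(raster.electrode_ids, electrodes)
    pooled = raster.spike_times_s[sel]

    bursts = []
    for s, e, p in merged:
        peak = rate[p]
        bound = baseline + boundary_frac * (peak - baseline)
        i = s
        while i > 0 and rate[i - 1] >= bound:
            i -= 1
        j = e
        while j < len(rate) - 1 and rate[j + 1] >= bound:
            j += 1
        onset = trace.times_s[i] - trace.dt / 2
        offset = trace.times_s[j] + trace.dt / 2
        n_spikes = int(np.count_nonzero((pooled >= onset) & (pooled <= offset)))
        bursts.append(
            NetworkBurst(
                peak_time_s=float(trace.times_s[p]),
                onset_s=float(onset),
                offset_s=float(offset),
                n_spikes=n_spikes,
                peak_rate=float(peak),
            )
        )
    # extension can make neighbours touch; keep bursts disjoint by clipping
    for a, b in zip(bursts[:-1], bursts[1:]):
        if a.offset_s > b.onset_s:
            mid = (a.peak_time_s + b.peak_time_s) / 2
            object.__setattr__(a, "offset_s", mid)
            object.__setattr__(b, "onset_s", mid)
    return bursts


def burst_metrics(
    bursts: list[NetworkBurst],
    div: int | None = None,
    chip_id: str = "",
    group_label: str = "",
) -> BurstMetrics:
    """Per-recording burst statistics; IBI is peak-to-peak and needs >= 2 bursts."""
    n = len(bursts)
    peaks = np.array([b.peak_time_s for b in bursts])
    if np.any(np.diff(peaks) < 0):
        raise ValidationError("bursts must be time-ordered")
    return BurstMetrics(
        n_bursts=n,
        spikes_per_burst=float(np.mean([b.n_spikes for b in bursts])) if n else float("nan"),
        inter_burst_interval_s=float(np.mean(np.diff(peaks))) if n >= 2 else float("nan"),
        burst_duration_s=float(np.mean([b.duration_s for b in bursts])) if n else float("nan"),
        div=div,
        chip_id=chip_id,
        group_label=group_label,
    )


def div_trajectory(metrics: list[BurstMetrics]) -> pd.DataFrame:
    """Mean ± SEM of each burst metric per (group, day in vitro).

    Output is long-form: one row per (group_label, div, metric) with columns
    ``mean, sem, n``; SEM is NaN for single-chip cells.
    """
    df = pd.DataFrame([m.as_dict() for m in metrics])
    value_cols = ["n_bursts", "spikes_per_burst", "inter_burst_interval_s", "burst_duration_s"]
    long = df.melt(
        id_vars=["group_label", "div", "chip_id"],
        value_vars=value_cols,
        var_name="metric",
        value_name="value",
    )
    out = (
        long.groupby(["group_label", "div", "metric"], sort=True)["value"]
        .agg(mean="mean", sem=lambda v: v.sem(ddof=1), n="count")
        .reset_index()
    )
    return out
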