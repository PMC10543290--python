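"""End-to-end orchestration: simulate or ingest cohorts, run every analysis
stage, and emit genotype-comparison reports as CSV bundles.

Both pipelines are fully deterministic under a fixed config: per-subject
seeds are derived from the base seed, and every output bundle embeds a
manifest with the resolved configuration so any file can be regenerated.

Simulated cohorts use common random numbers across genotypes: subject ``i``
of every group draws from the same stream, so the genotype contrast
isolates the preset parameter differences instead of riding on independent
sampling noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg_events, eeg_spectral, group_stats, mea_network, sleep_staging
from .errors import ValidationError
from .io_formats import read_edf, write_metrics_csv
from .synthetic_data import genotype_preset, simulate_eeg, simulate_raster

__all__ = ["EegRunConfig", "MeaRunConfig", "run_eeg_pipeline", "run_mea_pipeline"]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def _subject_seed(base: int, tag: str, index: int) -> int:
    """Derived seed; ``tag`` deliberately excludes the genotype (common
    random numbers across groups).  crc32 is stable across processes,
    unlike ``hash()`` on strings."""
    import zlib

    t = zlib.crc32(tag.encode()) % 997
    return (base * 10_007 + t * 1_000 + index) % _SEED_MOD


@dataclass
class EegRunConfig:
    """Telemetry-cohort run: simulated subjects per genotype, or EDF inputs."""

    outdir: str = "eeg_run"
    groups: tuple[str, ...] = ("WT", "HET")
    n_per_group: int = 8
    duration_s: float = 600.0
    epoch_len_s: float = 10.0
    seed: int = 0
    edf_paths: dict = field(default_factory=dict)  # group -> list of paths
    threshold_sd: float = 5.0
    max_gap_s: float = 2.0
    min_spikes: int = 3

    @classmethod
    def from_yaml(cls, path) -> "EegRunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if cfg.groups:
            cfg.groups = tuple(cfg.groups)
        return cfg


@dataclass
class MeaRunConfig:
    """Culture-cohort run: chips per genotype across days in vitro."""

    outdir: str = "mea_run"
    groups: tuple[str, ...] = ("WT", "HET")
    n_chips_per_group: int = 6
    divs: tuple[int, ...] = (17, 21, 27, 29, 35)
    duration_s: float = 300.0
    seed: int = 0
    scan_duration_s: float = 30.0
    n_top_electrodes: int = 256
    kernel_sigma_s: float = 0.05
    dt: float = 0.01
    posthoc_method: str = "sidak"

    @classmethod
    def from_yaml(cls, path) -> "MeaRunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.groups = tuple(cfg.groups)
        cfg.divs = tuple(cfg.divs)
        return cfg


def _analyze_recording(recording, config: EegRunConfig) -> dict:
    spectrum = eeg_spectral.compute_psd(recording)
    bands = eeg_spectral.band_power(spectrum)
    spikes = eeg_events.detect_spikes(recording, threshold_sd=config.threshold_sd)
    trains = eeg_events.group_spike_trains(
        spikes, max_gap_s=config.max_gap_s, min_spikes=config.min_spikes
    )
    summary = eeg_events.spike_train_summary(trains, recording.duration_s)
    features = sleep_staging.epoch_features(recording, config.epoch_len_s)
    hyp = sleep_staging.score_epochs(features, epoch_len_s=config.epoch_len_s)
    pct = sleep_staging.state_percentages(hyp)

    row = {
        "subject_id": recording.subject_id,
        "group_label": recording.group_label,
    }
    for _, b in bands.iterrows():
        row[f"{b['band']}_power_uv2"] = b["power_uv2"]
    row.update(summary)
    row.update(pct.as_dict())
    return row


def run_eeg_pipeline(config: EegRunConfig) -> dict:
    """Run PSD, band-power, spike-train and sleep analyses over a cohort.

    Returns a report dict with the per-subject metric table, the group
    comparisons, and the manifest; CSVs are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for group in config.groups:
        if config.edf_paths.get(group):
            recordings = [read_edf(p) for p in config.edf_paths[group]]
            for i, rec in enumerate(recordings):
                rec.group_label = group
                rec.subject_id = rec.subject_id or f"{group}_{i:02d}"
        else:
            recordings = []
            eeg_cfg, _ = genotype_preset(group)
            for i in range(config.n_per_group):
                cfg = replace(
                    eeg_cfg,
                    duration_s=config.duration_s,
                    epoch_len_s=config.epoch_len_s,
                    rng_seed=_subject_seed(config.seed, "eeg", i),
                )
                rec, _truth = simulate_eeg(
                    cfg, subject_id=f"{group}_{i:02d}", group_label=group
                )
                recordings.append(rec)
        for rec in recordings:
            logger.info("eeg: analyzing %s", rec.subject_id)
            rows.append(_analyze_recording(rec, config))

    metrics = pd.DataFrame(rows)
    write_metrics_csv(metrics, outdir / "subject_metrics.csv")

    comparisons, notice = _compare_groups(metrics, config.groups)
    write_metrics_csv(comparisons, outdir / "comparisons.csv")

    manifest = {
        "config": _jsonable(asdict(config)),
        "n_subjects": int(len(metrics)),
        "notice": notice,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"metrics": metrics, "comparisons": comparisons, "manifest": manifest}


def _compare_groups(metrics: pd.DataFrame, groups) -> tuple[pd.DataFrame, str]:
    value_cols = [
        c for c in metrics.columns if c not in ("subject_id", "group_label")
    ]
    if len(groups) < 2:
        return pd.DataFrame(columns=["metric"]), "single group: comparisons skipped"
    a_label, b_label = groups[0], groups[1]
    a = metrics[metrics["group_label"] == a_label]
    b = metrics[metrics["group_label"] == b_label]
    if len(a) < 3 or len(b) < 3:
        return (
            pd.DataFrame(columns=["metric"]),
            "fewer than 3 subjects per group: comparisons skipped",
        )
    rows = []
    for col in value_cols:
        va, _ = group_stats.filter_2sd(a[col].dropna().to_numpy())
        vb, _ = group_stats.filter_2sd(b[col].dropna().to_numpy())
        if len(va) < 2 or len(vb) < 2:
            continue
        res = group_stats.t_test(va, vb, labels=(a_label, b_label))
        rows.append(
            {
                "metric": col,
                f"mean_{a_label}": va.mean(),
                f"mean_{b_label}": vb.mean(),
                **res.as_dict(),
            }
        )
    return pd.DataFrame(rows), ""


def run_mea_pipeline(config: MeaRunConfig) -> dict:
    """Run the array pipeline per chip per DIV, then genotype x DIV statistics."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_metrics: list[mea_network.BurstMetrics] = []
    for group in config.groups:
        _, mea_cfg = genotype_preset(group)
        for div in config.divs:
            # culture maturation: burst frequency rises gently with age,
            # applied identically to both genotypes
            maturation = 1.0 + 0.03 * (div - min(config.divs))
            for chip in range(config.n_chips_per_group):
                cfg = replace(
                    mea_cfg,
                    duration_s=config.duration_s,
                    burst_rate_per_min=mea_cfg.burst_rate_per_min * maturation,
                    rng_seed=_subject_seed(config.seed, f"d{div}", chip),
                )
                raster, _truth = simulate_raster(cfg)
                scan = mea_network.activity_scan(raster, config.scan_duration_s)
                top = mea_network.select_top_electrodes(scan, config.n_top_electrodes)
                trace = mea_network.network_trace(
                    raster, top, config.kernel_sigma_s, config.dt
                )
                bursts = mea_network.detect_bursts(trace, raster, top)
                all_metrics.append(
                    mea_network.burst_metrics(
                        bursts, div=div, chip_id=f"{group}_d{div}_c{chip:02d}",
                        group_label=group,
                    )
                )

    metric_table = pd.DataFrame([m.as_dict() for m in all_metrics])
    write_metrics_csv(metric_table, outdir / "chip_metrics.csv")
    trajectory = mea_network.div_trajectory(all_metrics)
    write_metrics_csv(trajectory, outdir / "div_trajectory.csv")

    stats_rows = []
    if len(config.groups) >= 2 and config.n_chips_per_group >= 2:
        for metric in (
            "n_bursts",
            "spikes_per_burst",
            "inter_burst_interval_s",
            "burst_duration_s",
        ):
            sub = metric_table.rename(columns={metric: "value"})[
                ["chip_id", "group_label", "div", "value"]
            ]
            try:
                aov = group_stats.two_way_anova(sub)
            except ValidationError:
                continue
            for _, r in aov.iterrows():
                stats_rows.append({"metric": metric, **r.to_dict()})
            # per-DIV pairwise comparisons with multiplicity adjustment
            raw_p, divs_used = [], []
            for div in config.divs:
                cell = sub[sub["div"] == div]
                a = cell[cell["group_label"] == config.groups[0]]["value"].dropna()
                b = cell[cell["group_label"] == config.groups[1]]["value"].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    raw_p.append(group_stats.t_test(a, b).p_value)
                    divs_used.append(div)
            if raw_p:
                adj = group_stats.posthoc(raw_p, method=config.posthoc_method)
                for div, p, ap in zip(divs_used, raw_p, adj):
                    stats_rows.append(
                        {
                            "metric": metric,
                            "effect": f"{config.groups[0]} vs {config.groups[1]} @ DIV{div}",
                            "p_value": p,
                            "adjusted_p": ap,
                        }
                    )
    stats_table = pd.DataFrame(stats_rows)
    write_metrics_csv(stats_table, outdir / "stats.csv")

    manifest = {"config": _jsonable(asdict(config)), "n_chips": int(len(metric_table))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "metrics": metric_table,
        "trajectory": trajectory,
        "stats": stats_table,
        "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
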