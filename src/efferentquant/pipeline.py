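"""End-to-end orchestration: simulate -> measure -> analyze -> report.

The pipeline mirrors how the emulated study organises its results: per-group
ABR threshold trajectories and shifts, per-frequency morphometry and
field-normalised densitometry of efferent terminal buttons, immune-cell
counts, the statistical battery over those tables, and a size-OD correlation
table per experimental condition.  One integer seed fans out deterministically
to every stage through a ``numpy`` SeedSequence, so a manifest (config +
seed) regenerates the bundle bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abr import estimate_threshold, threshold_shift_table
from .quant import (
    button_density,
    count_immune_cells,
    default_calibration,
    densitometry_table,
    segment_buttons,
)
from .stats import (
    anova_oneway_posthoc,
    anova_twoway,
    correlation_table,
    friedman_with_posthoc,
    mann_whitney,
)
from .synthetic import StudyDesign, StudyDataset, simulate_study

log = logging.getLogger("efferentquant.pipeline")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_bundle"]


@dataclass(frozen=True)
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 0
    n_densitometry: int = 30
    threshold_policy: str = "minimal"
    # One global density threshold applied to every image, as in step-filter
    # calibrated acquisition; sits in the gray gap between stained terminals
    # and unstained structure across all conditions.  "auto" per-image
    # thresholding remains available.
    segmentation_threshold: float | str = 150.0
    run_icc: bool = True
    run_stats: bool = True
    baseline_day: int = 0


@dataclass
class ReportBundle:
    """All output tables of one pipeline run plus the reproducibility manifest."""

    thresholds: pd.DataFrame
    shifts: pd.DataFrame
    buttons: pd.DataFrame
    frame_summary: pd.DataFrame
    immune_counts: pd.DataFrame
    stats_results: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict
    stat_details: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "thresholds": self.thresholds,
            "shifts": self.shifts,
            "buttons": self.buttons,
            "frame_summary": self.frame_summary,
            "immune_counts": self.immune_counts,
            "stats_results": self.stats_results,
            "correlations": self.correlations,
        }


def _condition(group: str, terminal_day: int) -> str:
    if group in ("SC", "ES"):
        return group
    return f"{group}+1d" if terminal_day == 13 else f"{group}+14d"


def _measure_abr(dataset: StudyDataset, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for (animal, day), series in dataset.abr_series.items():
        res = estimate_threshold(series, policy=config.threshold_policy)
        rows.append(
            {
                "animal": animal,
                "group": series.meta.get("group"),
                "timepoint_day": day,
                "threshold_db": res.value_or_censor,
                "censored": res.censored,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["group", "animal", "timepoint_day"])
        .reset_index(drop=True)
    )


def _measure_icc(dataset: StudyDataset, config: PipelineConfig, seed_seq) -> tuple:
    cal = default_calibration()
    animals = dataset.animals.set_index("animal")
    btn_rows, frame_rows, immune_rows = [], [], []
    keys = sorted(dataset.frames)
    child_seeds = seed_seq.generate_state(len(keys))
    for (animal, f), sub_seed in zip(keys, child_seeds):
        frame = dataset.frames[(animal, f)]
        group = animals.loc[animal, "group"]
        terminal = int(animals.loc[animal, "terminal_day"])
        cond = _condition(group, terminal)
        segs = segment_buttons(frame, threshold=config.segmentation_threshold)
        dens = button_density(segs, frame.area_um2)
        sampled, fs = densitometry_table(
            frame, segs, cal, n=config.n_densitometry, seed=int(sub_seed)
        )
        for seg in sampled:
            btn_rows.append(
                {
                    "animal": animal,
                    "group": group,
                    "terminal_day": terminal,
                    "condition": cond,
                    "frequency_khz": f,
                    "area_um2": seg.area_um2,
                    "mean_gray": seg.mean_gray,
                    "od": seg.od,
                    "norm_od": seg.norm_od,
                }
            )
        areas = [s.area_um2 for s in segs]
        frame_rows.append(
            {
                "animal": animal,
                "group": group,
                "terminal_day": terminal,
                "condition": cond,
                "frequency_khz": f,
                "n_buttons": len(segs),
                "buttons_per_10k_um2": dens,
                "mean_area_um2": float(np.mean(areas)) if areas else np.nan,
                "mean_norm_od": float(np.mean([s.norm_od for s in sampled]))
                if sampled
                else np.nan,
                "field_mean_od": fs.mean_od,
                "field_sd_od": fs.sd_od,
            }
        )
        ic = count_immune_cells(frame, analyzed_length_um=frame.pixels.shape[1] * frame.pixel_pitch_um, cal=cal)
        immune_rows.append(
            {
                "animal": animal,
                "group": group,
                "terminal_day": terminal,
                "condition": cond,
                "frequency_khz": f,
                "ir_macrophages": ic.ir_macrophages,
                "monocytes": ic.monocytes,
                "macrophages_per_1000um": ic.macrophages_per_1000um,
                "monocytes_per_1000um": ic.monocytes_per_1000um,
            }
        )
    return (
        pd.DataFrame(btn_rows),
        pd.DataFrame(frame_rows),
        pd.DataFrame(immune_rows),
    )


def _run_stats(
    thresholds: pd.DataFrame, buttons: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rows, details = [], {}

    # Friedman within each group across timepoints, post hoc vs baseline day
    for g, sub in thresholds.groupby("group", sort=False):
        res = friedman_with_posthoc(
            sub,
            subject="animal",
            within="timepoint_day",
            value="threshold_db",
            comparisons="baseline",
            baseline=config.baseline_day,
        )
        details[f"friedman_{g}"] = res
        rows.append(
            {
                "test": "friedman",
                "scope": f"group={g}",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
        for _, pr in res.posthoc.iterrows():
            rows.append(
                {
                    "test": "friedman_posthoc",
                    "scope": f"group={g}, day {pr.level_a} vs {pr.level_b}",
                    "statistic": pr.statistic,
                    "p_value": pr.p_adj,
                    "significant": pr.p_adj < 0.05,
                }
            )

    # Mann-Whitney between groups at each timepoint
    groups = list(thresholds["group"].unique())
    for day, sub in thresholds.groupby("timepoint_day"):
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = sub.loc[sub["group"] == ga, "threshold_db"].to_numpy()
                b = sub.loc[sub["group"] == gb, "threshold_db"].to_numpy()
                if a.size == 0 or b.size == 0:
                    continue
                res = mann_whitney(a, b)
                rows.append(
                    {
                        "test": "mann_whitney",
                        "scope": f"day={day}, {ga} vs {gb}",
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )

    correlations = pd.DataFrame()
    if not buttons.empty:
        for metric in ("norm_od", "area_um2"):
            res = anova_oneway_posthoc(
                {
                    c: sub[metric].to_numpy()
                    for c, sub in buttons.groupby("condition", sort=False)
                },
                posthoc="games_howell",
            )
            details[f"anova_{metric}"] = res
            rows.append(
                {
                    "test": f"anova_oneway_{metric}",
                    "scope": "condition",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
        if buttons["frequency_khz"].nunique() > 1 and buttons["condition"].nunique() > 1:
            res2 = anova_twoway(buttons, "area_um2", "condition", "frequency_khz")
            details["anova_twoway_area"] = res2
            rows.append(
                {
                    "test": "anova_twoway_area",
                    "scope": "condition x frequency",
                    "statistic": res2.statistic,
                    "p_value": res2.p_value,
                    "significant": res2.significant,
                }
            )
        correlations = correlation_table(buttons, group_col="condition")
    return pd.DataFrame(rows), correlations, details


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every enabled stage in dependency order, deterministically."""
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_icc = ss.spawn(2)
    log.info("stage=simulate seed=%s", config.seed)
    dataset = simulate_study(config.design, seed=int(s_sim.generate_state(1)[0] % (2**31 - 1)))

    log.info("stage=abr series=%d", len(dataset.abr_series))
    thresholds = _measure_abr(dataset, config)
    shifts = threshold_shift_table(thresholds, baseline_day=config.baseline_day)

    if config.run_icc:
        log.info("stage=icc frames=%d", len(dataset.frames))
        buttons, frame_summary, immune = _measure_icc(dataset, config, s_icc)
    else:
        buttons = frame_summary = immune = pd.DataFrame()

    if config.run_stats:
        log.info("stage=stats")
        stats_results, correlations, details = _run_stats(thresholds, buttons, config)
    else:
        stats_results, correlations, details = pd.DataFrame(), pd.DataFrame(), {}

    manifest = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
    }
    return ReportBundle(
        thresholds=thresholds,
        shifts=shifts,
        buttons=buttons,
        frame_summary=frame_summary,
        immune_counts=immune,
        stats_results=stats_results,
        correlations=correlations,
        manifest=manifest,
        stat_details=details,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_bundle(bundle: ReportBundle, out_dir) -> Path:
    """Write every table as CSV plus the manifest as JSON; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return out
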