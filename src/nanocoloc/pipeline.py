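"""End-to-end orchestration: simulate, analyze, report.

A run is driven by a :class:`RunConfig` (constructible from YAML/JSON).
``run_simulate`` renders a synthetic experiment to an image directory with a
manifest; ``run_analyze`` takes any manifest-described image directory
through segmentation, QC, colocalization and condition-level statistics;
``run_full`` composes the two, so an analyze-mode rerun on simulated data
reproduces the full-mode results exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import io as io_mod
from . import segment as segment_mod
from . import stats as stats_mod
from .errors import ValidationError
from .synthetic import (
    ConditionLabel,
    SyntheticConfig,
    default_design,
    generate_fov,
)

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_cells: int = 5
    max_saturation: float = 0.01
    min_focus: float = 50.0
    min_per_condition: int = 110


@dataclass
class ColocOptions:
    n_sections: int = 100
    background_subtract: float = 0.0


@dataclass
class StatsOptions:
    alpha: float = 0.05
    adjustment: str = "bonferroni"


@dataclass
class RunConfig:
    design: dict[ConditionLabel, tuple[SyntheticConfig, int]] = field(default_factory=dict)
    output_dir: Path = Path("nanocoloc_out")
    input_dir: Path | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    coloc: ColocOptions = field(default_factory=ColocOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    master_seed: int = 0

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        base_kwargs = dict(doc.get("base_config", {}))
        for key in ("image_shape", "cell_radius_range"):
            if key in base_kwargs:
                base_kwargs[key] = tuple(base_kwargs[key])
        base = SyntheticConfig(**base_kwargs)
        design: dict[ConditionLabel, tuple[SyntheticConfig, int]] = {}
        if "default_design" in doc:
            dd = dict(doc["default_design"])
            design.update(
                default_design(
                    particle_size_nm=int(dd.get("particle_size_nm", 100)),
                    n_fovs=int(dd.get("n_fovs", 130)),
                    base_config=base,
                    include_4c=bool(dd.get("include_4c", False)),
                )
            )
        for entry in doc.get("design", []):
            entry = dict(entry)
            n_fovs = int(entry.pop("n_fovs", 1))
            overrides = entry.pop("overrides", {})
            cond = ConditionLabel(
                phenotype=entry["phenotype"],
                wash=entry.get("wash", "none"),
                particle_size_nm=int(entry.get("particle_size_nm", 100)),
                temperature_c=int(entry.get("temperature_c", 37)),
                replicate_id=str(entry.get("replicate_id", "r0")),
            )
            if cond in design:
                raise ValidationError(f"duplicate condition label {cond.key}")
            design[cond] = (base.replace(**overrides), n_fovs)
        return cls(
            design=design,
            output_dir=Path(doc.get("output_dir", "nanocoloc_out")),
            input_dir=Path(doc["input_dir"]) if doc.get("input_dir") else None,
            qc=QCThresholds(**doc.get("qc", {})),
            coloc=ColocOptions(**doc.get("coloc", {})),
            stats=StatsOptions(**doc.get("stats", {})),
            master_seed=int(doc.get("master_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping):
            raise ValidationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(doc)


def run_simulate(config: RunConfig, write_ground_truth: bool = True) -> Path:
    """Render the configured design into ``output_dir/images`` + manifest."""
    if not config.design:
        raise ValidationError("simulate requires a non-empty design")
    image_dir = Path(config.output_dir) / "images"
    image_dir.mkdir(parents=True, exist_ok=True)

    entries = [(cond, cfg, n) for cond, (cfg, n) in config.design.items()]
    seed_rng = np.random.Generator(np.random.PCG64(config.master_seed))
    rows = []
    n_total = 0
    for cond, cfg, n_fovs in entries:
        seeds = seed_rng.integers(0, 2**31, size=n_fovs)
        for j, s in enumerate(seeds):
            fov, gt = generate_fov(cfg.replace(seed=int(s)), cond)
            fov.fov_id = f"{cond.group}_{cond.replicate_id}_{j:04d}"
            rows.append(
                io_mod.write_fov(fov, image_dir, gt if write_ground_truth else None, seed=int(s))
            )
            n_total += 1
        logger.info("simulate: condition %s -> %d FOVs", cond.group, n_fovs)
    io_mod.write_manifest(rows, image_dir)
    logger.info("simulate: wrote %d FOVs to %s", n_total, image_dir)
    return image_dir


def _qc_frame(reports: list[segment_mod.QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fov_id": r.fov_id,
                "n_cells": r.n_cells,
                "saturation_fraction": r.saturation_fraction,
                "focus_metric": r.focus_metric,
                "passed": r.passed,
                "reasons": ";".join(r.reasons),
            }
            for r in reports
        ]
    )


def analyze_fovs(fovs: list, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment + QC every FOV, then colocalization on the passing subset.

    Returns (qc table, per-FOV colocalization table).
    """
    reports = []
    for fov in fovs:
        labels = segment_mod.segment_nuclei(fov.nuclei_channel)
        reports.append(
            segment_mod.assess_fov(
                fov,
                labels,
                min_cells=config.qc.min_cells,
                max_saturation=config.qc.max_saturation,
                min_focus=config.qc.min_focus,
            )
        )
    passing = segment_mod.filter_fovs(reports, fovs, config.qc.min_per_condition)
    logger.info("QC: %d of %d FOVs pass", len(passing), len(fovs))

    rows = []
    for fov in passing:
        res = coloc_mod.analyze_fov(
            fov,
            n_sections=config.coloc.n_sections,
            background_subtract=config.coloc.background_subtract,
        )
        row = {
            "fov_id": fov.fov_id,
            "group": fov.condition.group,
            "pearson_r": res.pearson_r,
            "overlap_R": res.overlap_R,
            "slope": res.slope,
            "intercept": res.intercept,
            "section_cc": res.section_cc,
            "n_pixels": res.n_pixels,
            "n_sections": res.n_sections,
        }
        row.update(fov.condition.to_dict())
        rows.append(row)
    return _qc_frame(reports), pd.DataFrame(rows)


def aggregate(coloc_df: pd.DataFrame, options: StatsOptions) -> dict[str, Any]:
    """Condition-level statistics from the per-FOV colocalization table.

    Separately for each particle size: pool the two control classes when
    statistically indistinguishable, summarize every condition, normalize
    condition means to the (pooled) control background, and build the
    pairwise comparison table.
    """
    if coloc_df.empty:
        raise ValidationError("no passing FOVs to aggregate")
    results: dict[str, Any] = {"per_size": {}}
    summaries: list[stats_mod.ConditionSummary] = []
    normalized: list[stats_mod.NormalizedSummary] = []

    for size, sub in coloc_df.groupby("particle_size_nm"):
        groups = {}
        for g, s in sub.groupby("group"):
            vals = s["pearson_r"].to_numpy()
            if len(vals) < 2:
                logger.warning(
                    "aggregate: condition %s retains %d FOV(s); too few to "
                    "summarize, dropping it", g, len(vals)
                )
                continue
            groups[str(g)] = vals
        if not groups:
            continue
        neg_key = next((g for g in groups if g.startswith("control_cells_only")), None)
        pos_key = next((g for g in groups if g.startswith("control_particles_only")), None)

        pooling = None
        comparison_groups = dict(groups)
        control_summary = None
        if neg_key and pos_key:
            pooling = stats_mod.combine_controls(
                groups[neg_key], groups[pos_key], alpha=options.alpha
            )
            if pooling.combined:
                comparison_groups.pop(neg_key)
                comparison_groups.pop(pos_key)
                control_name = f"Control_{size}nm"
                comparison_groups[control_name] = pooling.pooled
                control_summary = stats_mod.summarize_condition(pooling.pooled, control_name)
        elif neg_key or pos_key:
            key = neg_key or pos_key
            control_summary = stats_mod.summarize_condition(groups[key], key)

        size_summaries = [
            stats_mod.summarize_condition(v, k) for k, v in comparison_groups.items()
        ]
        summaries.extend(size_summaries)

        size_normalized = []
        if control_summary is not None and control_summary.mean_r > 0:
            for s in size_summaries:
                size_normalized.append(stats_mod.normalize_to_background(s, control_summary))
            normalized.extend(size_normalized)

        table = None
        if len(comparison_groups) >= 2:
            table = stats_mod.pairwise_comparisons(
                comparison_groups, alpha=options.alpha, adjustment=options.adjustment
            )
        results["per_size"][int(size)] = {
            "groups": comparison_groups,
            "pooling": pooling,
            "control_summary": control_summary,
            "summaries": size_summaries,
            "normalized": size_normalized,
            "comparisons": table,
        }

    if not results["per_size"]:
        raise ValidationError("no condition retained enough FOVs to summarize")
    results["summaries"] = summaries
    results["normalized"] = normalized
    return results


def _summary_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def run_analyze(config: RunConfig, image_dir: Path | None = None) -> dict[str, Any]:
    """Analyze a manifest-described image directory; write result tables."""
    image_dir = Path(image_dir or config.input_dir or Path(config.output_dir) / "images")
    fovs = io_mod.read_experiment(image_dir)
    if not fovs:
        raise ValidationError(f"manifest in {image_dir} lists no FOVs")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    qc_df, coloc_df = analyze_fovs(fovs, config)
    qc_df.to_csv(out_dir / "qc.csv", index=False)
    if coloc_df.empty:
        raise ValidationError("no FOVs passed QC in any condition")
    coloc_df.to_csv(out_dir / "coloc.csv", index=False)

    agg = aggregate(coloc_df, config.stats)
    _summary_frame(agg["summaries"]).to_csv(out_dir / "summary.csv", index=False)
    if agg["normalized"]:
        _summary_frame(agg["normalized"]).to_csv(out_dir / "normalized.csv", index=False)

    comparison_frames = []
    for size, res in agg["per_size"].items():
        if res["comparisons"] is not None:
            frame = res["comparisons"].to_frame()
            frame.insert(0, "particle_size_nm", size)
            comparison_frames.append(frame)
            res["comparisons"].to_matrix().to_csv(out_dir / f"comparison_matrix_{size}nm.csv")
    if comparison_frames:
        pd.concat(comparison_frames, ignore_index=True).to_csv(
            out_dir / "comparisons.csv", index=False
        )

    report = {
        "master_seed": config.master_seed,
        "image_dir": str(image_dir),
        "n_fovs_total": len(fovs),
        "n_fovs_passing": int(len(coloc_df)),
        "per_condition_counts": coloc_df.groupby("group").size().to_dict(),
        "per_size": {
            str(size): {
                "anova_p": res["comparisons"].anova_p if res["comparisons"] else None,
                "controls_pooled": bool(res["pooling"].combined) if res["pooling"] else None,
                "control_pooling_p": res["pooling"].p_value if res["pooling"] else None,
            }
            for size, res in agg["per_size"].items()
        },
        "qc_thresholds": dataclasses.asdict(config.qc),
        "coloc_options": dataclasses.asdict(config.coloc),
        "stats_options": dataclasses.asdict(config.stats),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    agg["report"] = report
    agg["qc"] = qc_df
    agg["coloc"] = coloc_df
    return agg


def run_full(config: RunConfig) -> dict[str, Any]:
    """Simulate the configured design, then analyze what was written."""
    image_dir = run_simulate(config)
    return run_analyze(config, image_dir=image_dir)
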