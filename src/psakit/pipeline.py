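"""End-to-end orchestration: cohort -> derivatives -> ethnicity annotation ->
summaries -> associations -> ROC cutoffs -> screening, rendered as CSV
artifacts plus a JSON run manifest.

All randomness flows from the single analysis seed through a
``numpy.random.SeedSequence`` spawned per stage, so a manifest (config +
seed) reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nhia
from .cohort import Cohort
from .config import AnalysisConfig
from .derivatives import add_derivatives
from .roc import (
    METRIC_COLUMNS,
    build_roc,
    compare_sensitivity_bootstrap,
    reports_to_frame,
    screening_classification,
    table3_report,
)
from .stats import association_report, group_comparison_pvalues, summarize_groups

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Aborts the run with the failing stage's name and context."""


def render_summary_table(summaries, pvalues: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long-format cohort-characteristics table: one row per variable x group
    with mean and median (min, max), plus categorical counts and the omnibus
    p-value per variable."""
    if not summaries:
        raise ValueError("cannot render an empty summary report")
    rows = []
    pmap = {}
    if pvalues is not None and len(pvalues):
        pmap = dict(zip(pvalues["variable"], pvalues["p_value"]))
    for s in summaries:
        for variable, row in s.continuous.iterrows():
            rows.append(
                {
                    "variable": variable,
                    "group": s.group,
                    "n": row["n"],
                    "mean": row["mean"],
                    "median": row["median"],
                    "min": row["min"],
                    "max": row["max"],
                    "p_value": pmap.get(variable),
                }
            )
        for cat_name, table in s.categorical.items():
            for level, row in table.iterrows():
                rows.append(
                    {
                        "variable": f"{cat_name}={level}",
                        "group": s.group,
                        "n": int(row["count"]),
                        "mean": None,
                        "median": None,
                        "min": None,
                        "max": None,
                        "p_value": pmap.get(cat_name),
                        "percent": row["percent"],
                    }
                )
    return pd.DataFrame(rows)


def render_table(report, style: str) -> pd.DataFrame:
    """Render a report in one of the publication-shaped table layouts.

    ``style="summary"`` expects a list of GroupSummary; ``style="cutoffs"``
    a list of CutoffReport (cutoffs rounded to per-metric printed precision,
    rates to 1 dp)."""
    if report is None or (hasattr(report, "__len__") and len(report) == 0):
        raise ValueError("cannot render an empty report")
    if style == "summary":
        return render_summary_table(report)
    if style == "cutoffs":
        return reports_to_frame(report, round_output=True)
    raise ValueError(f"unknown table style {style!r}; use 'summary' or 'cutoffs'")


def run_pipeline(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    surname_table: nhia.SurnameTable | None = None,
) -> dict:
    """Run every analysis stage on a cohort and (optionally) write the bundle.

    Returns a dict with the in-memory artifacts: the derived frame, summary
    tables, association report, cutoff reports, ROC curves, screening
    classifications, the fixed-specificity comparison, and the manifest.
    """
    config = config or AnalysisConfig()
    config.validate()
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(["bootstrap"], seed_root.spawn(1))}

    def _stage(name, fn, *args, **kwargs):
        logger.info("stage %s: starting", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        logger.info("stage %s: done", name)
        return result

    df = _stage("derive", lambda: add_derivatives(cohort.to_frame(), bsa_mode=config.bsa_mode,
                                                  tv_threshold=config.tv_threshold))
    logger.info("derive: %d records in, %d with BMI, %d with tumor volume",
                len(df), int(df["bmi"].notna().sum()), int(df["significant"].notna().sum()))

    table = surname_table or nhia.load_surname_table()
    df = _stage("nhia", nhia.annotate_cohort, df, table)

    summaries_race = _stage("summarize_race", summarize_groups, df, "race_ethnicity")
    pvalues_race = _stage("pvalues_race", group_comparison_pvalues, df, "race_ethnicity")
    summaries_inst = _stage("summarize_institution", summarize_groups, df, "institution",
                            None, ("race_ethnicity", "bmi_category"))
    pvalues_inst = _stage("pvalues_institution", group_comparison_pvalues, df, "institution",
                          None, ("race_ethnicity", "bmi_category"))

    associations = _stage("associate", association_report, df)

    reports = _stage("roc", table3_report, df, None, config.metrics,
                     "race_ethnicity", config.cutoff_criterion)
    roc_curves = {}
    for group, sub in df.groupby("race_ethnicity", sort=False):
        labeled = sub[sub["significant"].notna()]
        labels = labeled["significant"].to_numpy(dtype=bool)
        if labels.all() or not labels.any():
            continue
        for metric in config.metrics:
            col = METRIC_COLUMNS[metric]
            ok = labeled[col].notna().to_numpy()
            roc_curves[(str(group), metric)] = build_roc(
                labeled[col].to_numpy(float)[ok], labels[ok]
            )

    screenings = {}
    for metric, cutoff in config.published_cutoffs.items():
        screenings[metric] = _stage(
            f"screen_{metric}", screening_classification, df, metric, cutoff, config.tv_threshold
        )

    comparison = None
    labeled = df[df["significant"].notna() & df["psad"].notna() & df["psamd"].notna()]
    labels = labeled["significant"].to_numpy(dtype=bool)
    if labels.any() and not labels.all():
        comparison = _stage(
            "fixed_spec_comparison",
            compare_sensitivity_bootstrap,
            labeled["psamd"].to_numpy(float),
            labeled["psad"].to_numpy(float),
            labels,
            config.fixed_specificity,
            config.bootstrap_reps,
            np.random.default_rng(stage_seeds["bootstrap"]),
        )

    try:
        version = metadata.version("psakit")
    except metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "package": "psakit",
        "version": version,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_records": len(cohort),
        "provenance": cohort.provenance,
        "n_rejected_rows": len(cohort.rejected),
    }

    bundle = {
        "frame": df,
        "summary_race": summaries_race,
        "pvalues_race": pvalues_race,
        "summary_institution": summaries_inst,
        "pvalues_institution": pvalues_inst,
        "associations": associations,
        "cutoff_reports": reports,
        "roc_curves": roc_curves,
        "screenings": screenings,
        "fixed_spec_comparison": comparison,
        "manifest": manifest,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write the report bundle as CSV files plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_summary_table(bundle["summary_race"], bundle["pvalues_race"]).to_csv(
        out / "table1_by_race_ethnicity.csv", index=False
    )
    render_summary_table(bundle["summary_institution"], bundle["pvalues_institution"]).to_csv(
        out / "table2_by_institution.csv", index=False
    )
    bundle["associations"].to_csv(out / "associations.csv", index=False)
    reports_to_frame(bundle["cutoff_reports"], round_output=True).to_csv(
        out / "table3_optimal_cutoffs.csv", index=False
    )
    for (group, metric), roc in bundle["roc_curves"].items():
        roc.to_frame().to_csv(out / f"roc_points_{group}_{metric}.csv", index=False)
    for metric, screening in bundle["screenings"].items():
        screening.by_bmi_category.to_csv(out / f"screening_{metric}_by_bmi.csv")
        screening.by_pw_side.to_csv(out / f"screening_{metric}_by_pw.csv")
        pd.DataFrame([screening.counts]).to_csv(out / f"screening_{metric}_counts.csv", index=False)
    if bundle["fixed_spec_comparison"] is not None:
        pd.DataFrame([bundle["fixed_spec_comparison"]]).to_csv(
            out / "fixed_specificity_comparison.csv", index=False
        )
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2, default=str))
    logger.info("bundle written to %s", out)
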