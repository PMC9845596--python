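"""End-to-end orchestration: simulate/load → score → classify → analyze.

Artifacts written to the output directory:

* ``cohort.csv`` — scored, classified cohort in the dialect of :mod:`simscore.io`
* ``table1.csv`` — per-variable group comparisons (tidy, one row per variable)
* ``table2.csv`` — siMS mean ± SD per glycoregulation category and age group
* ``correlations.csv`` — siMS correlation screen (total and per group)
* ``report.md`` — human-readable echo of the two tables
* ``run_log.json`` — seed, package version, config hash, per-stage row counts

Runs are deterministic given the seed: identical seeds yield byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .classify import classify_dataframe
from .cohort import default_config, generate_cohort
from .errors import ConfigError
from .io import read_cohort, write_cohort
from .scores import score_dataframe
from .stats import benjamini_hochberg, build_correlations, build_table1, sims_by_glyco

logger = logging.getLogger(__name__)


def load_run_config(path) -> dict:
    """Pipeline configuration: YAML mapping with optional keys
    ``seed``, ``groups`` (list of {age_group, n}), ``bh``, ``welch``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a YAML mapping")
    return cfg


def simulate_study_cohort(seed: int, groups: Optional[list] = None) -> pd.DataFrame:
    """Both age-group cohorts at their published sizes, concatenated.

    Each group gets its own child seed derived from ``seed`` so the groups
    are independent but jointly reproducible.
    """
    if groups is None:
        groups = [{"age_group": "young"}, {"age_group": "older"}]
    frames = []
    for i, g in enumerate(groups):
        age_group = g["age_group"]
        child_seed = (int(seed) * 1_000_003 + i) % (2**31)
        cfg = default_config(age_group, n=g.get("n"), seed=child_seed)
        frames.append(generate_cohort(cfg, id_prefix=f"{age_group[0].upper()}"))
    return pd.concat(frames, ignore_index=True)


def analyze_cohort(df: pd.DataFrame, outdir: Path, bh: bool = False,
                   welch: bool = False, group_col: str = "age_group") -> dict:
    """Run the statistical surface on a scored, classified cohort and write
    the table artifacts. Returns the artifact path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = build_table1(df, group_col=group_col, welch=welch)
    table1 = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if bh:
        table1["p_adjusted_bh"] = benjamini_hochberg(table1["p_value"])

    table2 = sims_by_glyco(df, group_col=group_col)

    corr_rows = build_correlations(df, group_col=group_col)
    correlations = pd.DataFrame([dataclasses.asdict(r) for r in corr_rows])
    if bh and len(correlations):
        correlations["p_adjusted_bh"] = benjamini_hochberg(correlations["p_value"])

    paths = {
        "table1": outdir / "table1.csv",
        "table2": outdir / "table2.csv",
        "correlations": outdir / "correlations.csv",
        "report": outdir / "report.md",
    }
    table1.to_csv(paths["table1"], index=False)
    table2.to_csv(paths["table2"], index=False)
    correlations.to_csv(paths["correlations"], index=False)
    paths["report"].write_text(_render_report(table1, table2, correlations))
    return paths


def _sig(p) -> str:
    return " *" if (p is not None and not pd.isna(p) and p < 0.05) else ""


def _render_report(table1: pd.DataFrame, table2: pd.DataFrame,
                   correlations: pd.DataFrame) -> str:
    lines = ["# Cohort analysis report", "",
             "## Group comparisons", "",
             "| Variable | " +
             f"{table1['group1'].iloc[0]} | {table1['group2'].iloc[0]} | test | p |",
             "|---|---|---|---|---|"]
    for _, r in table1.iterrows():
        p = "" if pd.isna(r.p_value) else f"{r.p_value:.3g}"
        lines.append(
            f"| {r.label or r.variable} | {r.summary1} | {r.summary2} | "
            f"{r.test} | {p}{_sig(r.p_value)} |"
        )
    lines += ["", "## siMS score by glycoregulation category", "",
              "| Group | Category | n | siMS mean ± SD |", "|---|---|---|---|"]
    for _, r in table2.iterrows():
        sd = "—" if pd.isna(r.sims_sd) else f"{r.sims_sd:.2f}"
        lines.append(f"| {r.group} | {r.display} | {r.n} | {r.sims_mean:.2f} ± {sd} |")
    lines += ["", "## siMS correlation screen", "",
              "| Variable | Group | Method | r | p | n |", "|---|---|---|---|---|---|"]
    for _, r in correlations.iterrows():
        rr = "undefined" if pd.isna(r.r) else f"{r.r:.3f}"
        p = "" if pd.isna(r.p_value) else f"{r.p_value:.3g}"
        lines.append(
            f"| {r.y_variable} | {r.group} | {r.method} | {rr} | {p}{_sig(r.p_value)} "
            f"| {r.n_used} |"
        )
    lines += ["", "`*` p < 0.05 (annotation only)."]
    return "\n".join(lines) + "\n"


def run_pipeline(
    outdir,
    seed: int = 0,
    input_path=None,
    config_path=None,
    bh: bool = False,
    welch: bool = False,
) -> dict:
    """Full pipeline from a cohort CSV or a generator config; returns artifact
    paths. Deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg: dict = {}
    if config_path is not None:
        cfg = load_run_config(config_path)
        seed = int(cfg.get("seed", seed))

    if input_path is not None:
        df = read_cohort(input_path)
        source = {"input": str(input_path)}
    else:
        df = simulate_study_cohort(seed, groups=cfg.get("groups"))
        source = {"simulated_groups": cfg.get("groups") or "defaults"}
    n_raw = len(df)

    df = score_dataframe(df)
    df = classify_dataframe(df)
    cohort_path = outdir / "cohort.csv"
    write_cohort(df, cohort_path)

    paths = analyze_cohort(df, outdir, bh=bh or bool(cfg.get("bh")),
                           welch=welch or bool(cfg.get("welch")))
    paths["cohort"] = cohort_path

    log = {
        "seed": int(seed),
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps({**cfg, **source}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "source": source,
        "rows": {"input": n_raw, "scored": len(df)},
        "artifacts": {k: str(v) for k, v in paths.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    paths["run_log"] = log_path
    logger.info("pipeline complete: %d records, artifacts in %s", len(df), outdir)
    return paths
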