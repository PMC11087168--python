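"""Resumable study pipeline: generate -> metrics -> simulate -> study.

Every stage writes a CSV artifact; a rerun without ``force`` reuses any
readable artifact and re-runs (with a warning) stages whose cached CSV is
corrupted.  Partially-written files carry a ``.partial`` suffix until the
stage completes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from ..complexity.metrics import METRIC_NAMES, MetricVector, compute_all
from ..fluence_surrogate.fluence import GridSpec
from ..machine_plan.json_io import read_plan_json, write_plan_json
from ..machine_plan.types import Plan
from ..study.grid import (
    DeviationRecord,
    filter_parameters,
    run_grid,
    summarize_deviations,
)
from ..study.regression import RegressionResult, fit_metric_regressions, rank_metrics
from ..study.thresholds import derive_threshold
from ..synthetic_cohort.generator import generate_cohort
from .config import StudyConfig

log = logging.getLogger(__name__)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    partial = path.with_suffix(path.suffix + ".partial")
    frame.to_csv(partial, index=False)
    partial.replace(path)


def _cached_csv(path: Path, force: bool) -> Optional[pd.DataFrame]:
    if force or not path.exists():
        return None
    try:
        return pd.read_csv(path)
    except Exception:
        log.warning("cached %s is unreadable; re-running stage", path)
        return None


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_generate(config: StudyConfig, force: bool = False) -> List[Plan]:
    """Generate (or reload) the synthetic cohort as JSON plan files."""
    plans_dir = Path(config.out_dir) / "plans"
    plans_dir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    expected = spec.plans_per_site * len(spec.sites)
    cached = sorted(plans_dir.glob("*.json"))
    if not force and len(cached) == expected:
        try:
            return [read_plan_json(p) for p in cached]
        except Exception:
            log.warning("cached plans unreadable; regenerating")
    plans = generate_cohort(spec)
    for plan in plans:
        write_plan_json(plan, plans_dir / f"{plan.plan_id}.json")
    return plans


def stage_metrics(
    plans: List[Plan], out_dir: Path, force: bool = False
) -> Dict[str, MetricVector]:
    """Compute the 18 metrics per plan; cached as metrics.csv."""
    path = Path(out_dir) / "metrics.csv"
    frame = _cached_csv(path, force)
    if frame is not None and set(METRIC_NAMES) <= set(frame.columns):
        return {
            row["plan_id"]: MetricVector(**{m: row[m] for m in METRIC_NAMES})
            for _, row in frame.iterrows()
        }
    metrics = {plan.plan_id: compute_all(plan) for plan in plans}
    rows = []
    for plan in plans:
        row = {"plan_id": plan.plan_id, "site": plan.site_label}
        row.update(metrics[plan.plan_id].as_dict())
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path)
    return metrics


def stage_simulate(
    plans: List[Plan], config: StudyConfig, force: bool = False
) -> List[DeviationRecord]:
    """Run the perturbation grid; cached as deviations.csv."""
    path = Path(config.out_dir) / "deviations.csv"
    frame = _cached_csv(path, force)
    if frame is not None and len(frame):
        return [
            DeviationRecord(
                plan_id=str(r.plan_id),
                site_label=str(r.site_label),
                parameter=str(r.parameter),
                percentile=float(r.percentile),
                endpoint=str(r.endpoint),
                pct_deviation=float(r.pct_deviation),
            )
            for r in frame.itertuples()
        ]
    table = config.percentile_table()
    if config.binary_fluence:
        rows = {k: dict(v) for k, v in table.rows.items()}
        for name in ("source_sigma", "tg_width"):
            if name in rows:
                rows[name] = {p: 0.0 for p in rows[name]}
        table = type(table)(rows)
    records = run_grid(
        plans,
        table,
        parameters=config.parameters,
        percentiles=config.percentiles,
        grid_spec=GridSpec(resolution=config.resolution),
    )
    _write_csv(pd.DataFrame([r.__dict__ for r in records]), path)
    return records


def stage_study(
    records: List[DeviationRecord],
    metrics: Dict[str, MetricVector],
    config: StudyConfig,
    force: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Filter parameters, fit regressions, rank metrics, derive thresholds."""
    out_dir = Path(config.out_dir)
    kept = filter_parameters(
        records,
        dev_threshold=config.dev_threshold,
        contribution_threshold=config.contribution_threshold,
    )
    if not config.include_pdd and "pdd_slope_err" in kept:
        kept = [p for p in kept if p != "pdd_slope_err"]

    summary = summarize_deviations(records)
    _write_csv(summary, out_dir / "deviation_summary.csv")
    summary_site = summarize_deviations(records, by_site=True)
    _write_csv(summary_site, out_dir / "deviation_summary_by_site.csv")

    results = fit_metric_regressions(records, metrics, kept, dev_threshold=config.dev_threshold)
    reg_frame = pd.DataFrame([r.__dict__ for r in results])
    _write_csv(reg_frame, out_dir / "regressions.csv")

    ranking = rank_metrics(results)
    _write_csv(ranking, out_dir / "ranking.csv")

    thr_rows = []
    for res in results:
        if res.site_label != "all" or res.metric_name not in ("mean_gap", "tgi"):
            continue
        for limit in config.dose_limits:
            thr = derive_threshold(res, limit)
            if thr is not None:
                thr_rows.append(thr.__dict__)
    thresholds = pd.DataFrame(thr_rows)
    _write_csv(thresholds, out_dir / "thresholds.csv")

    return {
        "summary": summary,
        "summary_by_site": summary_site,
        "regressions": reg_frame,
        "ranking": ranking,
        "thresholds": thresholds,
        "kept_parameters": pd.DataFrame({"parameter": kept}),
    }


def run_all(config: StudyConfig, force: bool = False) -> Dict[str, pd.DataFrame]:
    """Full pipeline; writes a log file recording the seed and config hash."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "study.log").write_text(
        f"master_seed={config.master_seed}\nconfig_hash={_config_hash(config)}\n"
    )
    plans = stage_generate(config, force)
    metrics = stage_metrics(plans, out_dir, force)
    records = stage_simulate(plans, config, force)
    tables = stage_study(records, metrics, config, force)
    return tables
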