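"""Perturbation grid execution, deviation tabulation and parameter filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ..fluence_surrogate.deviation import (
    endpoint_deviations,
    roi_endpoints,
)
from ..fluence_surrogate.fluence import GridSpec, accumulate_plan_map, grid_for_plan
from ..fluence_surrogate.params import (
    PercentileTable,
    model_from_percentiles,
)
from ..fluence_surrogate.rois import rois_from_plan
from ..machine_plan.types import Plan

log = logging.getLogger(__name__)

STUDY_PERCENTILES = (2.5, 25.0, 75.0, 97.5)


@dataclass(frozen=True)
class DeviationRecord:
    plan_id: str
    site_label: str
    parameter: str
    percentile: float
    endpoint: str
    pct_deviation: float


def records_to_frame(records: Iterable[DeviationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def run_grid(
    cohort: Sequence[Plan],
    table: PercentileTable,
    parameters: Optional[Sequence[str]] = None,
    percentiles: Sequence[float] = STUDY_PERCENTILES,
    grid_spec: Optional[GridSpec] = None,
) -> List[DeviationRecord]:
    """Evaluate every plan x parameter x percentile perturbation.

    The baseline (all parameters at their 50th percentile) map and ROI set
    are computed once per plan.  Returns one record per endpoint of every
    (plan, parameter, percentile) cell, in deterministic order.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    parameters = list(parameters) if parameters is not None else table.parameters
    baseline = model_from_percentiles(table)
    records: List[DeviationRecord] = []
    for plan in cohort:
        grid = grid_for_plan(plan, grid_spec)
        rois = rois_from_plan(plan, grid=grid)
        map_b = accumulate_plan_map(plan, baseline, grid=grid)
        ep_b = roi_endpoints(map_b, rois, model=baseline, baseline=map_b)
        for parameter in parameters:
            for pct in percentiles:
                try:
                    model = model_from_percentiles(table, {parameter: pct})
                    map_p = accumulate_plan_map(plan, model, grid=grid.like(grid.values * 0))
                    ep_p = roi_endpoints(
                        map_p, rois, model=model, baseline=map_b, baseline_model=baseline
                    )
                    devs = endpoint_deviations(ep_p, ep_b)
                except Exception as exc:  # annotate failures with context
                    raise RuntimeError(
                        f"perturbation failed for plan={plan.plan_id} "
                        f"parameter={parameter} percentile={pct}: {exc}"
                    ) from exc
                for endpoint, dev in devs.items():
                    records.append(
                        DeviationRecord(
                            plan_id=plan.plan_id,
                            site_label=plan.site_label,
                            parameter=parameter,
                            percentile=float(pct),
                            endpoint=endpoint,
                            pct_deviation=dev,
                        )
                    )
    return records


def summarize_deviations(
    records: Iterable[DeviationRecord], by_site: bool = False
) -> pd.DataFrame:
    """Mean deviation and max |deviation| per (parameter, percentile, endpoint).

    MU-free aggregation over records; empty groups are simply absent.
    """
    frame = records_to_frame(list(records))
    if frame.empty:
        return frame
    keys = ["parameter", "percentile", "endpoint"] + (
        ["site_label"] if by_site else []
    )
    grouped = frame.groupby(keys)["pct_deviation"]
    out = grouped.agg(
        mean_deviation="mean",
        max_abs_deviation=lambda s: s.abs().max(),
        n="count",
    ).reset_index()
    return out


def count_exceeding_cells(
    records: Iterable[DeviationRecord],
    dev_threshold: float = 1.0,
    endpoint: str = "ctv_mean",
) -> Dict[str, int]:
    """Per-parameter count of (plan, parameter, percentile) cells whose
    ``endpoint`` deviation magnitude exceeds ``dev_threshold`` percent."""
    counts: Dict[str, int] = {}
    for rec in records:
        if rec.endpoint != endpoint:
            continue
        if abs(rec.pct_deviation) > dev_threshold:
            counts[rec.parameter] = counts.get(rec.parameter, 0) + 1
    return counts


def filter_parameters(
    records: Iterable[DeviationRecord],
    dev_threshold: float = 1.0,
    contribution_threshold: float = 0.10,
) -> List[str]:
    """Parameters contributing at least ``contribution_threshold`` of all
    above-threshold mean-CTV deviations.

    Counts cells with |ctv_mean deviation| > ``dev_threshold`` %, then keeps
    parameters whose count is >= contribution_threshold x grand total (the
    boundary counts as kept).  Returns parameters sorted by contribution,
    largest first; an empty grand total yields an empty list with a warning.
    """
    counts = count_exceeding_cells(list(records), dev_threshold)
    grand_total = sum(counts.values())
    if grand_total == 0:
        log.warning("no deviations exceed %.2f%%; parameter filter is empty", dev_threshold)
        return []
    kept = [
        (count, name)
        for name, count in counts.items()
        if count >= contribution_threshold * grand_total
    ]
    return [name for count, name in sorted(kept, key=lambda t: (-t[0], t[1]))]
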