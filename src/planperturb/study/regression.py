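"""Metric-vs-sensitivity regressions, ranking and threshold derivation.

Per plan and parameter, the response is the maximum over the four studied
percentile levels of the absolute mean-CTV percent deviation (both under-
and over-dose count).  Each complexity metric is regressed against that
response by ordinary least squares, per anatomical site and pooled, and
metrics are ranked by mean R-squared with weighted-R-squared and RMSE
confirmation rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..complexity.metrics import METRIC_NAMES, MetricVector
from .grid import DeviationRecord

UNDEFINED = float("nan")


@dataclass(frozen=True)
class RegressionResult:
    metric_name: str
    parameter: str
    site_label: str  # a site name or "all"
    slope: float
    intercept: float
    r_squared: float
    n: int
    rmse: float
    n_exceeding: int  # plans in this fit with response > 1% deviation


def ols_fit(x: np.ndarray, y: np.ndarray):
    """Plain least squares: slope, intercept, R^2, RMSE.

    Zero x-variance gives an undefined (NaN) fit marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx <= 0:
        return UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else UNDEFINED
    rmse = math.sqrt(ss_res / n)
    return slope, intercept, r2, rmse


def max_abs_ctv_deviation(
    records: Iterable[DeviationRecord],
) -> pd.DataFrame:
    """Per (plan, parameter): max over percentiles of |ctv_mean deviation|."""
    rows = [
        r.__dict__
        for r in records
        if r.endpoint == "ctv_mean" and not math.isnan(r.pct_deviation)
    ]
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["abs_dev"] = frame["pct_deviation"].abs()
    out = (
        frame.groupby(["plan_id", "site_label", "parameter"])["abs_dev"]
        .max()
        .reset_index()
        .rename(columns={"abs_dev": "max_abs_ctv_dev"})
    )
    return out


def fit_metric_regressions(
    records: Iterable[DeviationRecord],
    metrics: Mapping[str, MetricVector],
    parameters: Sequence[str],
    metric_names: Optional[Sequence[str]] = None,
    dev_threshold: float = 1.0,
    min_n: int = 3,
) -> List[RegressionResult]:
    """OLS of per-plan max |ctv_mean deviation| on each complexity metric.

    Fits are produced per anatomical site and pooled (site ``"all"``).
    Plans whose metric value is undefined (NaN) are excluded from that
    metric's fits; groups smaller than ``min_n`` are not reported.
    """
    metric_names = list(metric_names) if metric_names else METRIC_NAMES
    response = max_abs_ctv_deviation(list(records))
    results: List[RegressionResult] = []
    if response.empty:
        return results
    for parameter in parameters:
        sub = response[response["parameter"] == parameter]
        site_groups = [("all", sub)] + [
            (site, g) for site, g in sub.groupby("site_label")
        ]
        for metric_name in metric_names:
            for site, group in site_groups:
                xs, ys = [], []
                for _, row in group.iterrows():
                    mv = metrics.get(row["plan_id"])
                    if mv is None:
                        continue
                    x = getattr(mv, metric_name)
                    if math.isnan(x):
                        continue
                    xs.append(x)
                    ys.append(row["max_abs_ctv_dev"])
                if len(xs) < min_n:
                    continue
                slope, intercept, r2, rmse = ols_fit(np.array(xs), np.array(ys))
                results.append(
                    RegressionResult(
                        metric_name=metric_name,
                        parameter=parameter,
                        site_label=site,
                        slope=slope,
                        intercept=intercept,
                        r_squared=r2,
                        n=len(xs),
                        rmse=rmse,
                        n_exceeding=int(np.sum(np.array(ys) > dev_threshold)),
                    )
                )
    return results


def rank_metrics(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Aggregate fits per metric and rank by three schemes.

    ``mean_r2`` is the unweighted mean over (parameter, site) fits;
    ``weighted_r2`` weights each fit by its count of above-threshold plans;
    ``rmse`` is the mean fit RMSE.  Rank columns (1 = best) break ties by
    metric name, alphabetically.
    """
    rows: Dict[str, Dict[str, list]] = {}
    for res in results:
        entry = rows.setdefault(
            res.metric_name, {"r2": [], "w": [], "rmse": []}
        )
        if not math.isnan(res.r_squared):
            entry["r2"].append(res.r_squared)
            entry["w"].append(res.n_exceeding)
            entry["rmse"].append(res.rmse)
    table = []
    for name, entry in rows.items():
        r2 = np.array(entry["r2"], dtype=float)
        w = np.array(entry["w"], dtype=float)
        rmse = np.array(entry["rmse"], dtype=float)
        mean_r2 = float(r2.mean()) if r2.size else UNDEFINED
        weighted_r2 = float(np.dot(w, r2) / w.sum()) if r2.size and w.sum() > 0 else UNDEFINED
        mean_rmse = float(rmse.mean()) if rmse.size else UNDEFINED
        table.append(
            {
                "metric": name,
                "mean_r2": mean_r2,
                "weighted_r2": weighted_r2,
                "rmse": mean_rmse,
                "n_fits": int(r2.size),
            }
        )
    frame = pd.DataFrame(table)
    if frame.empty:
        return frame

    def _rank(col: str, ascending: bool) -> pd.Series:
        key = frame[col].fillna(-np.inf if not ascending else np.inf)
        order = sorted(
            frame.index,
            key=lambda i: (
                (key[i] if ascending else -key[i]),
                frame.loc[i, "metric"],
            ),
        )
        ranks = pd.Series(index=frame.index, dtype=int)
        for pos, idx in enumerate(order, start=1):
            ranks[idx] = pos
        return ranks

    frame["rank_mean_r2"] = _rank("mean_r2", ascending=False)
    frame["rank_weighted_r2"] = _rank("weighted_r2", ascending=False)
    frame["rank_rmse"] = _rank("rmse", ascending=True)
    return frame.sort_values("rank_mean_r2").reset_index(drop=True)
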