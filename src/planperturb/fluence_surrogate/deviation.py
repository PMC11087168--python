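"""ROI endpoint readout and percent dose deviations."""

from __future__ import annotations

import math
from typing import Dict, Optional

import numpy as np

from ..machine_plan.types import Plan
from .fluence import FluenceGrid, GridSpec, accumulate_plan_map, grid_for_plan
from .params import BeamModelParams
from .rois import RoiSet, rois_from_plan

ENDPOINTS = [
    "ctv_mean",
    "oar_mean",
    "oar_near_max",
    "ctv_min",
    "ctv_max",
    "ctv_d95",
    "coverage",
]

UNDEFINED = float("nan")


def _depth_factor(model: Optional[BeamModelParams], depth_cm: float) -> float:
    if model is None:
        return 1.0
    return 1.0 + model.pdd_slope_err * (depth_cm - 10.0)


def roi_endpoints(
    fluence: FluenceGrid,
    rois: RoiSet,
    model: Optional[BeamModelParams] = None,
    baseline: Optional[FluenceGrid] = None,
    baseline_model: Optional[BeamModelParams] = None,
) -> Dict[str, float]:
    """Dose-proxy endpoints per ROI.

    Percentile-based proxies stand in for volumetric endpoints: near-max is
    the 98th percentile of serial-OAR pixels, ctv_min/max the 0.2nd/99.8th
    CTV percentiles and D95 the 5th.  ``coverage`` (fraction of CTV pixels
    at or above 98% of the baseline CTV median) requires ``baseline``.
    The per-ROI depth (PDD) modifier of ``model`` is applied here.
    """
    ctv = fluence.values[rois.ctv] * _depth_factor(model, rois.depths["ctv"])
    oar_p = fluence.values[rois.oar_parallel] * _depth_factor(
        model, rois.depths["oar_parallel"]
    )
    oar_s = fluence.values[rois.oar_serial] * _depth_factor(
        model, rois.depths["oar_serial"]
    )
    out = {
        "ctv_mean": float(np.mean(ctv)),
        "oar_mean": float(np.mean(oar_p)),
        # hottest-2% proxy: take the next pixel up, not an interpolated value
        "oar_near_max": float(np.percentile(oar_s, 98.0, method="higher")),
        "ctv_min": float(np.percentile(ctv, 0.2)),
        "ctv_max": float(np.percentile(ctv, 99.8)),
        "ctv_d95": float(np.percentile(ctv, 5.0)),
    }
    if baseline is not None:
        base_ctv = baseline.values[rois.ctv] * _depth_factor(
            baseline_model if baseline_model is not None else model,
            rois.depths["ctv"],
        )
        ref = 0.98 * float(np.median(base_ctv))
        out["coverage"] = float(np.mean(ctv >= ref))
    else:
        out["coverage"] = UNDEFINED
    return out


def endpoint_deviations(
    perturbed_endpoints: Dict[str, float], baseline_endpoints: Dict[str, float]
) -> Dict[str, float]:
    """100 * (perturbed - baseline) / baseline; positive = overdose."""
    out: Dict[str, float] = {}
    for name in ENDPOINTS:
        b = baseline_endpoints.get(name, UNDEFINED)
        p = perturbed_endpoints.get(name, UNDEFINED)
        if b == 0 or math.isnan(b) or math.isnan(p):
            out[name] = UNDEFINED
        else:
            out[name] = 100.0 * (p - b) / b
    return out


def dose_deviation(
    plan: Plan,
    perturbed: BeamModelParams,
    baseline: BeamModelParams,
    rois: Optional[RoiSet] = None,
    grid_spec: Optional[GridSpec] = None,
) -> Dict[str, float]:
    """Percent deviation per endpoint of ``perturbed`` vs ``baseline`` model."""
    grid = grid_for_plan(plan, grid_spec)
    if rois is None:
        rois = rois_from_plan(plan, grid=grid)
    map_b = accumulate_plan_map(plan, baseline, grid=grid.like(grid.values))
    map_p = accumulate_plan_map(plan, perturbed, grid=grid.like(grid.values))
    ep_b = roi_endpoints(map_b, rois, model=baseline, baseline=map_b)
    ep_p = roi_endpoints(
        map_p, rois, model=perturbed, baseline=map_b, baseline_model=baseline
    )
    return endpoint_deviations(ep_p, ep_b)
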