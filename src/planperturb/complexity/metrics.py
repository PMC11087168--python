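"""The 18 plan-complexity metrics.

All control-point averages are MU-weighted.  A leaf pair contributes only
while "active" (gap above the machine's minimum dynamic gap and y-extent
inside the open jaw window).  Metrics that cannot be evaluated (no active
pairs, too few control points, ...) return the explicit undefined marker
``UNDEFINED`` (NaN) — never silently zero.

Conventions fixed here (and mirrored by the naive oracles in the test
suite):

* tongue-and-groove index: junctions require both adjacent pairs active;
  the denominator is the mean of the two pair gaps floored at 0.1 mm, and
  the per-junction ratio is clamped at 1.
* interdigitation: the junction count denominator is all 59 junctions,
  but only junctions between two active pairs can register a crossing.
* "modulation" of a dynamics quantity is its MU-weighted standard
  deviation over delivery intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Dict, List, Tuple

import numpy as np

from ..machine_plan.types import Beam, ControlPoint, Plan
from ..machine_plan.errors import MalformedPlanError

UNDEFINED = float("nan")

TGI_GAP_FLOOR = 0.1  # mm
MI_ACCEL_REF = 100.0  # mm/s^2
MI_DOSE_RATE_REF = 60.0  # MU/min
MI_GANTRY_SPEED_REF = 1.0  # deg/s

METRIC_NAMES = [
    "mcs",
    "mi_total",
    "plan_irregularity",
    "plan_modulation",
    "edge_metric",
    "lt_per_al",
    "tgi",
    "interdigitation_fraction",
    "mean_mlc_speed",
    "mlc_speed_modulation",
    "mean_dose_rate",
    "dose_rate_modulation",
    "mean_gantry_speed",
    "gantry_speed_modulation",
    "mean_gap",
    "q1_gap",
    "total_mu",
    "n_arcs",
]


@dataclass
class MetricVector:
    mcs: float
    mi_total: float
    plan_irregularity: float
    plan_modulation: float
    edge_metric: float
    lt_per_al: float
    tgi: float
    interdigitation_fraction: float
    mean_mlc_speed: float
    mlc_speed_modulation: float
    mean_dose_rate: float
    dose_rate_modulation: float
    mean_gantry_speed: float
    gantry_speed_modulation: float
    mean_gap: float
    q1_gap: float
    total_mu: float
    n_arcs: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# ---------------------------------------------------------------------------
# helpers

def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted quantile with linear interpolation between order statistics."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    # mid-point positions of each weighted sample in [0, 1]
    pos = (cw - 0.5 * w) / total
    return float(np.interp(q, pos, v))


def _clipped_rows(beam: Beam, cp: ControlPoint):
    """Per-pair jaw-clipped open x-intervals and row heights.

    Returns (active, left, right, height); inactive or fully-clipped rows
    have zero length/height.
    """
    geom = beam.machine
    b = geom.leaf_boundaries
    active = beam.active_pairs(cp)
    left = np.maximum(cp.bank_a_positions, cp.jaw_x1)
    right = np.minimum(cp.bank_b_positions, cp.jaw_x2)
    open_len = np.maximum(right - left, 0.0)
    ok = active & (open_len > 0)
    y_lo = np.maximum(b[:-1], cp.jaw_y1)
    y_hi = np.minimum(b[1:], cp.jaw_y2)
    height = np.maximum(y_hi - y_lo, 0.0)
    left = np.where(ok, left, 0.0)
    right = np.where(ok, right, 0.0)
    height = np.where(ok, height, 0.0)
    return ok, left, right, height


def _aperture_area(beam: Beam, cp: ControlPoint) -> float:
    ok, left, right, height = _clipped_rows(beam, cp)
    return float(np.sum((right - left) * height))


# ---------------------------------------------------------------------------
# gap metrics

def gap_metrics(beam: Beam) -> Tuple[float, float]:
    """MU-weighted mean MLC gap and first quartile of the gap distribution."""
    weights = beam.mu_weights()
    cp_means, cp_w = [], []
    pooled_gaps, pooled_w = [], []
    for cp, w in zip(beam.control_points, weights):
        active = beam.active_pairs(cp)
        if not np.any(active):
            continue
        gaps = cp.gaps[active]
        cp_means.append(float(np.mean(gaps)))
        cp_w.append(w)
        pooled_gaps.append(gaps)
        pooled_w.append(np.full(gaps.shape, w))
    if not cp_means or sum(cp_w) <= 0:
        return UNDEFINED, UNDEFINED
    cp_w_arr = np.array(cp_w)
    mean_gap = float(np.dot(cp_w_arr, cp_means) / cp_w_arr.sum())
    q1 = _weighted_quantile(
        np.concatenate(pooled_gaps), np.concatenate(pooled_w), 0.25
    )
    return mean_gap, q1


# ---------------------------------------------------------------------------
# tongue-and-groove index

def tgi(beam: Beam) -> float:
    """MU-weighted mean adjacent-position/gap ratio over junctions and banks."""
    weights = beam.mu_weights()
    num = 0.0
    den = 0.0
    for cp, w in zip(beam.control_points, weights):
        active = beam.active_pairs(cp)
        both = active[:-1] & active[1:]
        if not np.any(both):
            continue
        gaps = cp.gaps
        gmean = np.maximum((gaps[:-1] + gaps[1:]) / 2.0, TGI_GAP_FLOOR)
        ratios = []
        for bank in (cp.bank_a_positions, cp.bank_b_positions):
            diff = np.abs(bank[:-1] - bank[1:])
            ratios.append(np.minimum(diff[both] / gmean[both], 1.0))
        num += w * float(np.mean(np.concatenate(ratios)))
        den += w
    return num / den if den > 0 else UNDEFINED


# ---------------------------------------------------------------------------
# modulation complexity score

def _lsv_bank(positions: np.ndarray) -> float:
    n = len(positions)
    if n <= 1:
        return 1.0
    pos_max = float(positions.max() - positions.min())
    if pos_max <= 0:
        return 1.0
    diffs = np.abs(np.diff(positions))
    return float(np.sum(pos_max - diffs) / ((n - 1) * pos_max))


def mcs(beam: Beam) -> float:
    """Modulation complexity score: MU-weighted sum of AAV x LSV per CP."""
    geom = beam.machine
    widths = np.asarray(geom.leaf_widths)
    gaps_all = np.stack([np.maximum(cp.gaps, 0.0) for cp in beam.control_points])
    max_gaps = gaps_all.max(axis=0)
    denom = float(np.dot(max_gaps, widths))
    if denom <= 0:
        return UNDEFINED
    weights = beam.mu_weights()
    score = 0.0
    for cp, w, gaps in zip(beam.control_points, weights, gaps_all):
        aav = float(np.dot(gaps, widths)) / denom
        active = beam.active_pairs(cp)
        if np.any(active):
            lsv_a = _lsv_bank(-cp.bank_a_positions[active])  # negated: larger = wider open
            lsv_b = _lsv_bank(cp.bank_b_positions[active])
            lsv = lsv_a * lsv_b
        else:
            lsv = 1.0
        score += w * aav * lsv
    return float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# aperture shape metrics

def _cp_perimeter_area(beam: Beam, cp: ControlPoint) -> Tuple[float, float]:
    ok, left, right, height = _clipped_rows(beam, cp)
    lengths = right - left
    area = float(np.sum(lengths * height))
    if area <= 0:
        return 0.0, 0.0
    perim = float(np.sum(2.0 * height[ok]))
    # horizontal exposed edges at every leaf boundary (including caps)
    n = len(lengths)
    for i in range(n + 1):
        la = lengths[i - 1] if i - 1 >= 0 else 0.0
        lb = lengths[i] if i < n else 0.0
        if la > 0 and lb > 0:
            overlap = max(
                0.0,
                min(right[i - 1], right[i]) - max(left[i - 1], left[i]),
            )
            perim += la + lb - 2.0 * overlap
        else:
            perim += la + lb
    return perim, area


def plan_irregularity(beam: Beam) -> float:
    """MU-weighted aperture irregularity P^2 / (4 pi A) of the rectilinear aperture."""
    weights = beam.mu_weights()
    num = 0.0
    den = 0.0
    for cp, w in zip(beam.control_points, weights):
        perim, area = _cp_perimeter_area(beam, cp)
        if area <= 0:
            continue  # zero-area CPs excluded, weights renormalized below
        num += w * (perim**2) / (4.0 * math.pi * area)
        den += w
    return num / den if den > 0 else UNDEFINED


def edge_metric(beam: Beam) -> float:
    """Exposed leaf-side edge length (between active pairs) per aperture area, 1/mm."""
    weights = beam.mu_weights()
    num = 0.0
    den = 0.0
    for cp, w in zip(beam.control_points, weights):
        ok, left, right, height = _clipped_rows(beam, cp)
        lengths = right - left
        area = float(np.sum(lengths * height))
        if area <= 0:
            continue
        edge = 0.0
        for i in range(len(lengths) - 1):
            if ok[i] and ok[i + 1]:
                overlap = max(
                    0.0, min(right[i], right[i + 1]) - max(left[i], left[i + 1])
                )
                edge += lengths[i] + lengths[i + 1] - 2.0 * overlap
        num += w * edge / area
        den += w
    return num / den if den > 0 else UNDEFINED


def _union_length(intervals: List[Tuple[float, float]]) -> float:
    ivs = sorted((l, r) for l, r in intervals if r > l)
    total = 0.0
    cur_l, cur_r = None, None
    for l, r in ivs:
        if cur_r is None or l > cur_r:
            if cur_r is not None:
                total += cur_r - cur_l
            cur_l, cur_r = l, r
        else:
            cur_r = max(cur_r, r)
    if cur_r is not None:
        total += cur_r - cur_l
    return total


def plan_modulation(beam: Beam) -> float:
    """1 - (MU-weighted aperture area) / (area of the union of all CP apertures)."""
    geom = beam.machine
    n = geom.leaf_pair_count
    per_pair: List[List[Tuple[float, float]]] = [[] for _ in range(n)]
    heights = np.zeros(n)
    weights = beam.mu_weights()
    weighted_area = 0.0
    for cp, w in zip(beam.control_points, weights):
        ok, left, right, height = _clipped_rows(beam, cp)
        weighted_area += w * float(np.sum((right - left) * height))
        for i in np.nonzero(ok)[0]:
            per_pair[i].append((left[i], right[i]))
            heights[i] = max(heights[i], height[i])
    union_area = float(
        sum(_union_length(per_pair[i]) * heights[i] for i in range(n))
    )
    if union_area <= 0:
        return UNDEFINED
    pm = 1.0 - weighted_area / union_area
    # summation-order noise for a static aperture must read as exactly 0
    return 0.0 if abs(pm) < 1e-12 else pm


# ---------------------------------------------------------------------------
# travel, interdigitation

def lt_per_al(beam: Beam) -> float:
    """Mean leaf travel per unit arc length (VMAT) or per control point."""
    if beam.n_cp < 2:
        return 0.0
    ever_active = np.zeros(beam.machine.leaf_pair_count, dtype=bool)
    for cp in beam.control_points:
        ever_active |= beam.active_pairs(cp)
    if not np.any(ever_active):
        return UNDEFINED
    bank_a = np.stack([cp.bank_a_positions for cp in beam.control_points])
    bank_b = np.stack([cp.bank_b_positions for cp in beam.control_points])
    travel_a = np.sum(np.abs(np.diff(bank_a, axis=0)), axis=0)[ever_active]
    travel_b = np.sum(np.abs(np.diff(bank_b, axis=0)), axis=0)[ever_active]
    mean_travel = float(np.mean(np.concatenate([travel_a, travel_b])))
    denom = beam.arc_span if beam.arc_span > 0 else (beam.n_cp - 1)
    return mean_travel / denom


def interdigitation_fraction(beam: Beam, tol: float = 1e-9) -> float:
    """MU-weighted fraction of leaf junctions with crossed opposing tips."""
    n_junctions = beam.machine.leaf_pair_count - 1
    weights = beam.mu_weights()
    total = 0.0
    for cp, w in zip(beam.control_points, weights):
        active = beam.active_pairs(cp)
        both = active[:-1] & active[1:]
        xa, xb = cp.bank_a_positions, cp.bank_b_positions
        crossed = (xa[:-1] > xb[1:] + tol) | (xa[1:] > xb[:-1] + tol)
        total += w * float(np.count_nonzero(crossed & both)) / n_junctions
    return total


# ---------------------------------------------------------------------------
# dynamics

def _interval_quantities(beam: Beam):
    """Per-interval dt, MU increments, leaf speeds, dose rate and gantry speed."""
    cps = beam.control_points
    cmf = np.array([cp.cumulative_mu_fraction for cp in cps])
    t = np.array([cp.nominal_time for cp in cps])
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise MalformedPlanError("nominal_time must be strictly increasing")
    dmu = np.diff(cmf) * beam.total_mu
    bank_a = np.stack([cp.bank_a_positions for cp in cps])
    bank_b = np.stack([cp.bank_b_positions for cp in cps])
    speeds_a = np.abs(np.diff(bank_a, axis=0)) / dt[:, None]
    speeds_b = np.abs(np.diff(bank_b, axis=0)) / dt[:, None]
    dose_rate = dmu / dt * 60.0
    gantry = np.array([cp.gantry_angle for cp in cps])
    gantry_speed = np.abs(np.diff(gantry)) / dt
    active = np.stack([beam.active_pairs(cp) for cp in cps])
    interval_active = active[:-1] | active[1:]
    return dt, dmu, speeds_a, speeds_b, dose_rate, gantry_speed, interval_active


def _wmean_wstd(values: np.ndarray, weights: np.ndarray) -> Tuple[float, float]:
    wsum = weights.sum()
    if wsum <= 0:
        return 0.0, 0.0
    mean = float(np.dot(weights, values) / wsum)
    var = float(np.dot(weights, (values - mean) ** 2) / wsum)
    return mean, math.sqrt(max(var, 0.0))


def dynamics_metrics(beam: Beam) -> Dict[str, float]:
    """MU-weighted mean / standard deviation of MLC speed, dose rate, gantry speed."""
    zero = {
        "mean_mlc_speed": 0.0,
        "mlc_speed_modulation": 0.0,
        "mean_dose_rate": 0.0,
        "dose_rate_modulation": 0.0,
        "mean_gantry_speed": 0.0,
        "gantry_speed_modulation": 0.0,
    }
    if beam.technique == "static-IMRT" or beam.n_cp < 2:
        return zero
    dt, dmu, speeds_a, speeds_b, dose_rate, gantry_speed, interval_active = (
        _interval_quantities(beam)
    )
    leaf_vals, leaf_w = [], []
    for k in range(len(dt)):
        mask = interval_active[k]
        if not np.any(mask):
            continue
        vals = np.concatenate([speeds_a[k][mask], speeds_b[k][mask]])
        leaf_vals.append(vals)
        leaf_w.append(np.full(vals.shape, dmu[k]))
    if leaf_vals:
        ms, ss = _wmean_wstd(np.concatenate(leaf_vals), np.concatenate(leaf_w))
    else:
        ms, ss = 0.0, 0.0
    mdr, sdr = _wmean_wstd(dose_rate, dmu)
    mgs, sgs = _wmean_wstd(gantry_speed, dmu)
    return {
        "mean_mlc_speed": ms,
        "mlc_speed_modulation": ss,
        "mean_dose_rate": mdr,
        "dose_rate_modulation": sdr,
        "mean_gantry_speed": mgs,
        "gantry_speed_modulation": sgs,
    }


# ---------------------------------------------------------------------------
# modulation index

def modulation_index_total(
    beam: Beam,
    accel_ref: float = MI_ACCEL_REF,
    dose_rate_ref: float = MI_DOSE_RATE_REF,
    gantry_speed_ref: float = MI_GANTRY_SPEED_REF,
    n_points: int = 100,
) -> float:
    """Penalty-weighted integral of the leaf-speed-change exceedance curve.

    z(f) is the (penalty-weighted) fraction of per-leaf speed changes with
    magnitude >= f * sigma; the index is the trapezoidal integral of z over
    f in [0, 1].  A beam with zero speed-change spread scores 0.
    """
    if beam.technique == "static-IMRT":
        return 0.0
    if beam.n_cp < 3:
        return UNDEFINED
    dt, dmu, speeds_a, speeds_b, dose_rate, gantry_speed, interval_active = (
        _interval_quantities(beam)
    )
    speeds = np.concatenate([speeds_a, speeds_b], axis=1)  # intervals x 120
    active2 = np.concatenate([interval_active, interval_active], axis=1)
    dv = np.diff(speeds, axis=0)
    use = active2[:-1] & active2[1:]
    if not np.any(use):
        return UNDEFINED
    # mid-interval time step for accelerations
    mid_dt = (dt[:-1] + dt[1:]) / 2.0
    accel = np.abs(dv) / mid_dt[:, None]
    d_dr = np.abs(np.diff(dose_rate))
    d_gs = np.abs(np.diff(gantry_speed))
    penalty = (
        (1.0 + accel / accel_ref)
        * (1.0 + d_dr[:, None] / dose_rate_ref)
        * (1.0 + d_gs[:, None] / gantry_speed_ref)
    )
    changes = np.abs(dv[use])
    weights = penalty[use]
    sigma = float(np.std(dv[use]))  # spread of the signed speed changes
    if sigma <= 0:
        return 0.0
    fs = np.linspace(0.0, 1.0, n_points)
    wsum = weights.sum()
    z = np.array(
        [float(np.sum(weights[changes >= f * sigma])) / wsum for f in fs]
    )
    return float(np.trapezoid(z, fs))


# ---------------------------------------------------------------------------
# plan-level aggregation

def beam_metrics(beam: Beam) -> Dict[str, float]:
    mean_gap, q1 = gap_metrics(beam)
    out = {
        "mcs": mcs(beam),
        "mi_total": modulation_index_total(beam),
        "plan_irregularity": plan_irregularity(beam),
        "plan_modulation": plan_modulation(beam),
        "edge_metric": edge_metric(beam),
        "lt_per_al": lt_per_al(beam),
        "tgi": tgi(beam),
        "interdigitation_fraction": interdigitation_fraction(beam),
        "mean_gap": mean_gap,
        "q1_gap": q1,
    }
    out.update(dynamics_metrics(beam))
    return out


def compute_all(plan: Plan) -> MetricVector:
    """Per-beam metrics combined by MU-weighted mean; MU and arcs summed.

    Undefined (NaN) beam values propagate to the plan value.
    """
    beam_mu = np.array([b.total_mu for b in plan.beams], dtype=float)
    w = beam_mu / beam_mu.sum()
    per_beam = [beam_metrics(b) for b in plan.beams]
    averaged = {
        name: float(np.dot(w, [bm[name] for bm in per_beam]))
        for name in per_beam[0]
    }
    averaged["total_mu"] = float(beam_mu.sum())
    averaged["n_arcs"] = float(plan.n_arcs)
    return MetricVector(**averaged)
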