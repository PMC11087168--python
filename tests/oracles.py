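"""Independent naive-loop oracles for the complexity metrics and regressions.

Everything here is written as plain Python loops (shapely for polygon
geometry, pixel counting for edges) so that the vectorized implementations
are checked against genuinely separate code paths.  The documented metric
conventions (MU weighting, active-pair rules, clamps) are restated by hand.
"""

from __future__ import annotations

import math

from shapely.geometry import box
from shapely.ops import unary_union

TGI_FLOOR = 0.1


def cp_weights(beam):
    cmf = [cp.cumulative_mu_fraction for cp in beam.control_points]
    if len(cmf) == 1:
        return [1.0]
    if beam.technique == "static-IMRT":
        out = []
        prev = 0.0
        for c in cmf:
            out.append(c - prev)
            prev = c
        return out
    w = [0.0] * len(cmf)
    for k in range(len(cmf) - 1):
        inc = cmf[k + 1] - cmf[k]
        w[k] += inc / 2
        w[k + 1] += inc / 2
    return w


def active_mask(beam, cp):
    b = beam.machine.leaf_boundaries
    out = []
    for i in range(beam.machine.leaf_pair_count):
        gap = cp.bank_b_positions[i] - cp.bank_a_positions[i]
        y_overlap = (b[i + 1] > cp.jaw_y1) and (b[i] < cp.jaw_y2)
        out.append(bool(gap > beam.machine.min_dynamic_gap and y_overlap))
    return out


def oracle_mean_gap(beam):
    num = den = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        gaps = [
            cp.bank_b_positions[i] - cp.bank_a_positions[i]
            for i in range(len(act))
            if act[i]
        ]
        if not gaps:
            continue
        num += w * sum(gaps) / len(gaps)
        den += w
    return num / den if den > 0 else math.nan


def oracle_q1_gap(beam):
    samples = []
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        for i in range(len(act)):
            if act[i]:
                samples.append(
                    (cp.bank_b_positions[i] - cp.bank_a_positions[i], w)
                )
    if not samples:
        return math.nan
    samples.sort(key=lambda t: t[0])
    total = sum(w for _, w in samples)
    cum = 0.0
    pts = []
    for v, w in samples:
        cum += w
        pts.append(((cum - 0.5 * w) / total, v))
    q = 0.25
    if q <= pts[0][0]:
        return pts[0][1]
    if q >= pts[-1][0]:
        return pts[-1][1]
    for (p0, v0), (p1, v1) in zip(pts, pts[1:]):
        if p0 <= q <= p1:
            if p1 == p0:
                return v1
            return v0 + (v1 - v0) * (q - p0) / (p1 - p0)
    raise AssertionError("unreachable")


def oracle_tgi(beam):
    num = den = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        ratios = []
        for bank in (cp.bank_a_positions, cp.bank_b_positions):
            for i in range(len(act) - 1):
                if act[i] and act[i + 1]:
                    g_i = cp.bank_b_positions[i] - cp.bank_a_positions[i]
                    g_j = cp.bank_b_positions[i + 1] - cp.bank_a_positions[i + 1]
                    denom = max((g_i + g_j) / 2.0, TGI_FLOOR)
                    ratios.append(min(abs(bank[i] - bank[i + 1]) / denom, 1.0))
        if ratios:
            num += w * sum(ratios) / len(ratios)
            den += w
    return num / den if den > 0 else math.nan


def oracle_mcs(beam):
    n = beam.machine.leaf_pair_count
    widths = beam.machine.leaf_widths
    max_gaps = [0.0] * n
    for cp in beam.control_points:
        for i in range(n):
            gap = max(cp.bank_b_positions[i] - cp.bank_a_positions[i], 0.0)
            max_gaps[i] = max(max_gaps[i], gap)
    denom = sum(g * w for g, w in zip(max_gaps, widths))
    if denom <= 0:
        return math.nan

    def lsv(positions):
        if len(positions) <= 1:
            return 1.0
        pos_max = max(positions) - min(positions)
        if pos_max <= 0:
            return 1.0
        acc = 0.0
        for a, b in zip(positions, positions[1:]):
            acc += pos_max - abs(a - b)
        return acc / ((len(positions) - 1) * pos_max)

    score = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        aav = (
            sum(
                max(cp.bank_b_positions[i] - cp.bank_a_positions[i], 0.0) * widths[i]
                for i in range(n)
            )
            / denom
        )
        idx = [i for i in range(n) if act[i]]
        if idx:
            la = lsv([-cp.bank_a_positions[i] for i in idx])
            lb = lsv([cp.bank_b_positions[i] for i in idx])
            score += w * aav * la * lb
        else:
            score += w * aav
    return min(max(score, 0.0), 1.0)


def _cp_row_boxes(beam, cp):
    b = beam.machine.leaf_boundaries
    act = active_mask(beam, cp)
    boxes = []
    for i in range(len(act)):
        if not act[i]:
            continue
        left = max(cp.bank_a_positions[i], cp.jaw_x1)
        right = min(cp.bank_b_positions[i], cp.jaw_x2)
        lo = max(b[i], cp.jaw_y1)
        hi = min(b[i + 1], cp.jaw_y2)
        if right > left and hi > lo:
            boxes.append(box(left, lo, right, hi))
    return boxes


def oracle_plan_irregularity(beam):
    num = den = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        boxes = _cp_row_boxes(beam, cp)
        if not boxes:
            continue
        union = unary_union(boxes)
        area = union.area
        if area <= 0:
            continue
        perim = union.length
        num += w * perim**2 / (4 * math.pi * area)
        den += w
    return num / den if den > 0 else math.nan


def oracle_edge_metric(beam, dx: float = 0.05):
    """Pixel-count oracle: exposed side-edge length between active pairs."""
    num = den = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        b = beam.machine.leaf_boundaries
        area = 0.0
        for i in range(len(act)):
            if not act[i]:
                continue
            left = max(cp.bank_a_positions[i], cp.jaw_x1)
            right = min(cp.bank_b_positions[i], cp.jaw_x2)
            lo = max(b[i], cp.jaw_y1)
            hi = min(b[i + 1], cp.jaw_y2)
            if right > left and hi > lo:
                area += (right - left) * (hi - lo)
        if area <= 0:
            continue
        edge = 0.0
        x_lo = min(cp.bank_a_positions) - 1.0
        x_hi = max(cp.bank_b_positions) + 1.0
        n_bins = int((x_hi - x_lo) / dx) + 1
        for i in range(len(act) - 1):
            if not (act[i] and act[i + 1]):
                continue

            def open_at(j, x):
                left = max(cp.bank_a_positions[j], cp.jaw_x1)
                right = min(cp.bank_b_positions[j], cp.jaw_x2)
                return left <= x <= right and right > left

            count = 0
            for k in range(n_bins):
                x = x_lo + (k + 0.5) * dx
                if open_at(i, x) != open_at(i + 1, x):
                    count += 1
            edge += count * dx
        num += w * edge / area
        den += w
    return num / den if den > 0 else math.nan


def oracle_plan_modulation(beam):
    union_boxes = []
    weighted_area = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        boxes = _cp_row_boxes(beam, cp)
        union_boxes.extend(boxes)
        weighted_area += w * sum(bx.area for bx in boxes)
    if not union_boxes:
        return math.nan
    union_area = unary_union(union_boxes).area
    if union_area <= 0:
        return math.nan
    return 1.0 - weighted_area / union_area


def oracle_lt_per_al(beam):
    if len(beam.control_points) < 2:
        return 0.0
    n = beam.machine.leaf_pair_count
    ever = [False] * n
    for cp in beam.control_points:
        act = active_mask(beam, cp)
        for i in range(n):
            ever[i] = ever[i] or act[i]
    travels = []
    for i in range(n):
        if not ever[i]:
            continue
        for bank_attr in ("bank_a_positions", "bank_b_positions"):
            travel = 0.0
            prev = None
            for cp in beam.control_points:
                x = getattr(cp, bank_attr)[i]
                if prev is not None:
                    travel += abs(x - prev)
                prev = x
            travels.append(travel)
    if not travels:
        return math.nan
    denom = beam.arc_span if beam.arc_span > 0 else len(beam.control_points) - 1
    return sum(travels) / len(travels) / denom


def oracle_interdigitation(beam, tol: float = 1e-9):
    n_j = beam.machine.leaf_pair_count - 1
    total = 0.0
    for cp, w in zip(beam.control_points, cp_weights(beam)):
        act = active_mask(beam, cp)
        count = 0
        for i in range(n_j):
            if not (act[i] and act[i + 1]):
                continue
            if (
                cp.bank_a_positions[i] > cp.bank_b_positions[i + 1] + tol
                or cp.bank_a_positions[i + 1] > cp.bank_b_positions[i] + tol
            ):
                count += 1
        total += w * count / n_j
    return total


def _weighted_mean_std(pairs):
    wsum = sum(w for _, w in pairs)
    if wsum <= 0:
        return 0.0, 0.0
    mean = sum(v * w for v, w in pairs) / wsum
    var = sum(w * (v - mean) ** 2 for v, w in pairs) / wsum
    return mean, math.sqrt(max(var, 0.0))


def oracle_dynamics(beam):
    zero = {
        "mean_mlc_speed": 0.0,
        "mlc_speed_modulation": 0.0,
        "mean_dose_rate": 0.0,
        "dose_rate_modulation": 0.0,
        "mean_gantry_speed": 0.0,
        "gantry_speed_modulation": 0.0,
    }
    cps = beam.control_points
    if beam.technique == "static-IMRT" or len(cps) < 2:
        return zero
    speed_pairs, dr_pairs, gs_pairs = [], [], []
    for k in range(len(cps) - 1):
        a, b = cps[k], cps[k + 1]
        dt = b.nominal_time - a.nominal_time
        dmu = (b.cumulative_mu_fraction - a.cumulative_mu_fraction) * beam.total_mu
        act_a = active_mask(beam, a)
        act_b = active_mask(beam, b)
        for i in range(beam.machine.leaf_pair_count):
            if act_a[i] or act_b[i]:
                for attr in ("bank_a_positions", "bank_b_positions"):
                    v = abs(getattr(b, attr)[i] - getattr(a, attr)[i]) / dt
                    speed_pairs.append((v, dmu))
        dr_pairs.append((dmu / dt * 60.0, dmu))
        gs_pairs.append((abs(b.gantry_angle - a.gantry_angle) / dt, dmu))
    ms, ss = _weighted_mean_std(speed_pairs)
    mdr, sdr = _weighted_mean_std(dr_pairs)
    mgs, sgs = _weighted_mean_std(gs_pairs)
    return {
        "mean_mlc_speed": ms,
        "mlc_speed_modulation": ss,
        "mean_dose_rate": mdr,
        "dose_rate_modulation": sdr,
        "mean_gantry_speed": mgs,
        "gantry_speed_modulation": sgs,
    }


def oracle_mi_total(
    beam, accel_ref=100.0, dose_rate_ref=60.0, gantry_speed_ref=1.0, n_points=100
):
    cps = beam.control_points
    if beam.technique == "static-IMRT":
        return 0.0
    if len(cps) < 3:
        return math.nan
    n = beam.machine.leaf_pair_count
    act = [active_mask(beam, cp) for cp in cps]
    dts, dose_rates, gantry_speeds = [], [], []
    for k in range(len(cps) - 1):
        a, b = cps[k], cps[k + 1]
        dt = b.nominal_time - a.nominal_time
        dts.append(dt)
        dmu = (b.cumulative_mu_fraction - a.cumulative_mu_fraction) * beam.total_mu
        dose_rates.append(dmu / dt * 60.0)
        gantry_speeds.append(abs(b.gantry_angle - a.gantry_angle) / dt)
    changes, weights = [], []
    for k in range(len(cps) - 2):
        mid_dt = (dts[k] + dts[k + 1]) / 2.0
        d_dr = abs(dose_rates[k + 1] - dose_rates[k])
        d_gs = abs(gantry_speeds[k + 1] - gantry_speeds[k])
        for i in range(n):
            iv1 = act[k][i] or act[k + 1][i]
            iv2 = act[k + 1][i] or act[k + 2][i]
            if not (iv1 and iv2):
                continue
            for attr in ("bank_a_positions", "bank_b_positions"):
                v1 = abs(
                    getattr(cps[k + 1], attr)[i] - getattr(cps[k], attr)[i]
                ) / dts[k]
                v2 = abs(
                    getattr(cps[k + 2], attr)[i] - getattr(cps[k + 1], attr)[i]
                ) / dts[k + 1]
                dv = v2 - v1
                accel = abs(dv) / mid_dt
                penalty = (
                    (1 + accel / accel_ref)
                    * (1 + d_dr / dose_rate_ref)
                    * (1 + d_gs / gantry_speed_ref)
                )
                changes.append(dv)
                weights.append(penalty)
    if not changes:
        return math.nan
    mean = sum(changes) / len(changes)
    sigma = math.sqrt(sum((c - mean) ** 2 for c in changes) / len(changes))
    if sigma <= 0:
        return 0.0
    wsum = sum(weights)
    zs = []
    fs = [j / (n_points - 1) for j in range(n_points)]
    for f in fs:
        zs.append(
            sum(w for c, w in zip(changes, weights) if abs(c) >= f * sigma) / wsum
        )
    integral = 0.0
    for j in range(n_points - 1):
        integral += (zs[j] + zs[j + 1]) / 2.0 * (fs[j + 1] - fs[j])
    return integral


def oracle_beam_metrics(beam):
    mg = oracle_mean_gap(beam)
    out = {
        "mcs": oracle_mcs(beam),
        "mi_total": oracle_mi_total(beam),
        "plan_irregularity": oracle_plan_irregularity(beam),
        "plan_modulation": oracle_plan_modulation(beam),
        "edge_metric": oracle_edge_metric(beam),
        "lt_per_al": oracle_lt_per_al(beam),
        "tgi": oracle_tgi(beam),
        "interdigitation_fraction": oracle_interdigitation(beam),
        "mean_gap": mg,
        "q1_gap": oracle_q1_gap(beam),
    }
    out.update(oracle_dynamics(beam))
    return out


def oracle_compute_all(plan):
    mus = [b.total_mu for b in plan.beams]
    total = sum(mus)
    per_beam = [oracle_beam_metrics(b) for b in plan.beams]
    out = {}
    for name in per_beam[0]:
        out[name] = sum(
            bm[name] * mu / total for bm, mu in zip(per_beam, mus)
        )
    out["total_mu"] = total
    out["n_arcs"] = float(
        sum(1 for b in plan.beams if b.technique == "VMAT-arc")
    )
    return out


def oracle_ols(xs, ys):
    """Naive-summation least squares: slope, intercept, r2."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((y - slope * x - intercept) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - ybar) ** 2 for y in ys)
    r2 = 1 - ss_res / ss_tot
    return slope, intercept, r2
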