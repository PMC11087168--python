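"""Seeded synthetic plan and cohort generation.

Trajectory model: a shared bounded Gaussian random walk carries the aperture
centre across the sweep window; each leaf pair adds an independent bounded
walk whose amplitude is set by the preset's ``adjacency_roughness`` (this is
what drives adjacent-pair decorrelation and hence the tongue-and-groove
index).  Per-control-point gaps are log-normal around a plan-level target
drawn from the preset's mean-gap range, smoothed along the leaf-pair axis.
MU fractions come from a Dirichlet draw.  Dynamic timing respects a maximum
gantry speed, dose rate and leaf speed.

All randomness flows from one seed; identical (preset, seed) inputs give
bit-identical plans.
"""

from __future__ import annotations

from typing import List, Sequence, Union

import numpy as np

from ..complexity.metrics import gap_metrics
from ..machine_plan.types import Beam, ControlPoint, MachineGeometry, Plan
from .fixtures import _field_pairs
from .presets import CohortSpec, SitePreset

MAX_GANTRY_SPEED = 6.0  # deg/s
MAX_DOSE_RATE = 600.0  # MU/min
MAX_LEAF_SPEED = 25.0  # mm/s

SeedLike = Union[int, Sequence[int]]


class CalibrationError(RuntimeError):
    def __init__(self, message: str, best_value: float):
        super().__init__(message)
        self.best_value = best_value


def _bounded_walk(rng_normals: np.ndarray, scale: float, bound: float) -> np.ndarray:
    """Unit-variance-normalized cumulative walk, scaled and clipped to +/- bound."""
    n = len(rng_normals)
    walk = np.cumsum(rng_normals) / np.sqrt(np.arange(1, n + 1))
    walk = walk - walk.mean()
    return np.clip(walk * scale, -bound, bound)


def _smooth_pairs(arr: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving average along the leaf-pair axis (axis 0)."""
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(arr, ((pad, pad), (0, 0)), mode="edge")
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, "valid"), 0, padded)


def plan_mean_gap(plan: Plan) -> float:
    """MU-weighted plan-level mean gap (beam values weighted by beam MU)."""
    mus = np.array([b.total_mu for b in plan.beams])
    vals = np.array([gap_metrics(b)[0] for b in plan.beams])
    return float(np.dot(mus, vals) / mus.sum())


def generate_plan(preset: SitePreset, seed: SeedLike, plan_id: str | None = None) -> Plan:
    """Generate one reproducible synthetic plan from a site preset."""
    geom = MachineGeometry()
    if preset.target_mean_gap_range[1] >= preset.sweep_extent:
        raise ValueError("infeasible preset: gap target exceeds sweep extent")
    rng = np.random.default_rng(seed)

    gap_target = float(rng.uniform(*preset.target_mean_gap_range))
    roughness_u = float(rng.uniform(0.6, 1.4))
    inside = _field_pairs(geom, preset.field_length)
    n_pairs = geom.leaf_pair_count
    n_cp = preset.cp_count
    static = preset.technique == "static-IMRT"

    beams: List[Beam] = []
    for bi in range(preset.n_beams):
        mu = float(rng.uniform(*preset.mu_range))
        shared_normals = rng.normal(size=n_cp)
        pair_normals = rng.normal(size=(n_pairs, n_cp))
        gap_normals = rng.normal(size=(n_pairs, n_cp))
        alpha = np.full(max(n_cp - 1, 1), 5.0)
        incs = rng.dirichlet(alpha)

        half_range = max((preset.sweep_extent - gap_target) / 2.0, 1.0)
        shared = _bounded_walk(shared_normals, preset.sweep_extent / 5.0, half_range)

        sigma_o = preset.adjacency_roughness * roughness_u * gap_target * 0.5
        offsets = np.empty((n_pairs, n_cp))
        for i in range(n_pairs):
            offsets[i] = _bounded_walk(pair_normals[i], sigma_o, 3.0 * sigma_o + 1e-9)

        sigma_g = preset.gap_dispersion
        log_noise = _smooth_pairs(gap_normals) * sigma_g - sigma_g**2 / 2.0
        gaps = gap_target * np.exp(log_noise)
        gaps = np.clip(gaps, geom.min_dynamic_gap * 2.0, preset.sweep_extent)

        centers = shared[None, :] + offsets
        bank_a = np.where(inside[:, None], centers - gaps / 2.0, 0.0)
        bank_b = np.where(inside[:, None], centers + gaps / 2.0, 0.0)
        limit = geom.max_leaf_position - 1.0
        bank_a = np.clip(bank_a, -limit, limit)
        bank_b = np.clip(bank_b, bank_a, limit)

        if static:
            cmf = np.cumsum(rng.dirichlet(np.full(n_cp, 5.0)))
            cmf[-1] = 1.0
            times = np.arange(n_cp, dtype=float) * 2.0
            gantry = np.full(n_cp, (360.0 * bi / preset.n_beams + 180.0) % 360.0 - 180.0)
            dose_rates = np.zeros(n_cp)
        else:
            cmf = np.concatenate([[0.0], np.cumsum(incs)])
            cmf[-1] = 1.0
            gantry = np.linspace(
                -preset.arc_span / 2.0, preset.arc_span / 2.0, n_cp
            )
            dmu = np.diff(cmf) * mu
            dang = np.abs(np.diff(gantry))
            dx_max = np.max(
                np.abs(np.diff(np.concatenate([bank_a, bank_b]), axis=1)), axis=0
            )
            dt = np.maximum.reduce(
                [
                    dang / MAX_GANTRY_SPEED,
                    dmu / (MAX_DOSE_RATE / 60.0),
                    dx_max / MAX_LEAF_SPEED,
                ]
            )
            dt = np.maximum(dt, 1e-3)
            times = np.concatenate([[0.0], np.cumsum(dt)])
            rates = dmu / dt * 60.0
            dose_rates = np.concatenate([[rates[0]], rates])

        jaw_margin = 5.0
        open_a = bank_a[inside]
        open_b = bank_b[inside]
        jaw_x1 = float(open_a.min() - jaw_margin)
        jaw_x2 = float(open_b.max() + jaw_margin)
        jaw_y1 = -preset.field_length / 2.0
        jaw_y2 = preset.field_length / 2.0

        cps = [
            ControlPoint(
                cumulative_mu_fraction=float(cmf[k]),
                gantry_angle=float(gantry[k]),
                bank_a_positions=bank_a[:, k].copy(),
                bank_b_positions=bank_b[:, k].copy(),
                jaw_x1=jaw_x1,
                jaw_x2=jaw_x2,
                jaw_y1=jaw_y1,
                jaw_y2=jaw_y2,
                nominal_time=float(times[k]),
                dose_rate=float(dose_rates[k]),
            )
            for k in range(n_cp)
        ]
        beams.append(
            Beam(
                control_points=cps,
                total_mu=mu,
                technique=preset.technique,  # type: ignore[arg-type]
                machine=geom,
                arc_span=preset.arc_span,
                name=f"{preset.site_label}-b{bi + 1}",
            )
        )

    plan = Plan(
        plan_id=plan_id or f"{preset.site_label}-s{seed}",
        site_label=preset.site_label,
        beams=beams,
    )
    return calibrate_to_targets(plan, gap_target, tol=0.02)


def calibrate_to_targets(
    plan: Plan, target_mean_gap: float, tol: float = 0.02, max_iter: int = 20
) -> Plan:
    """Rescale gap widths about their centres until the plan mean gap hits target.

    Aperture centres and MU weights are preserved; only leaf pairs that are
    open (gap above the dynamic minimum) are rescaled.  Raises
    :class:`CalibrationError` (carrying the best-achieved value) if the
    relative error does not reach ``tol`` within ``max_iter`` iterations.
    """
    best = plan_mean_gap(plan)
    for _ in range(max_iter):
        current = plan_mean_gap(plan)
        rel = abs(current - target_mean_gap) / target_mean_gap
        if rel <= tol:
            return plan
        factor = target_mean_gap / current
        for beam in plan.beams:
            limit = beam.machine.max_leaf_position - 1.0
            open_thresh = beam.machine.min_dynamic_gap
            for cp in beam.control_points:
                gaps = cp.gaps
                mask = gaps > open_thresh
                centers = (cp.bank_a_positions + cp.bank_b_positions) / 2.0
                new_gaps = np.where(mask, gaps * factor, gaps)
                cp.bank_a_positions = np.clip(centers - new_gaps / 2.0, -limit, limit)
                cp.bank_b_positions = np.clip(centers + new_gaps / 2.0, -limit, limit)
        best = plan_mean_gap(plan)
    if abs(best - target_mean_gap) / target_mean_gap > tol:
        raise CalibrationError(
            f"mean-gap calibration did not converge (best {best:.3f} mm, "
            f"target {target_mean_gap:.3f} mm)",
            best_value=best,
        )
    return plan


def generate_cohort(spec: CohortSpec) -> List[Plan]:
    """Generate ``plans_per_site`` plans for every site preset.

    Child seeds are derived from ``(master_seed, site_index, plan_index)``
    so cohorts are reproducible regardless of generation order.
    """
    plans: List[Plan] = []
    for si, preset in enumerate(spec.sites):
        for pi in range(spec.plans_per_site):
            plan = generate_plan(
                preset,
                seed=(spec.master_seed, si, pi),
                plan_id=f"{preset.site_label}-{pi + 1:02d}",
            )
            plans.append(plan)
    return plans
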