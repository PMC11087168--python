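"""Analytic plan fixtures: static rectangular fields and sliding windows."""

from __future__ import annotations

import numpy as np

from ..machine_plan.types import Beam, ControlPoint, MachineGeometry, Plan


def _field_pairs(geom: MachineGeometry, field_length: float) -> np.ndarray:
    """Pairs whose y-extent lies fully within +/- field_length/2."""
    b = geom.leaf_boundaries
    return (b[:-1] >= -field_length / 2 - 1e-9) & (b[1:] <= field_length / 2 + 1e-9)


def make_static_field(
    gap: float,
    field_length: float,
    mu: float,
    geom: MachineGeometry | None = None,
    plan_id: str = "static-field",
) -> Plan:
    """Single-aperture rectangular field: ``gap`` x ``field_length`` mm.

    All pairs inside the field open symmetrically at +/- gap/2; the rest are
    parked closed on the axis, behind the closed Y jaws.
    """
    geom = geom or MachineGeometry()
    if gap <= 0:
        raise ValueError("gap must be > 0")
    if gap > 2 * geom.max_leaf_position:
        raise ValueError("gap exceeds the maximum field size")
    inside = _field_pairs(geom, field_length)
    bank_a = np.where(inside, -gap / 2, 0.0)
    bank_b = np.where(inside, gap / 2, 0.0)
    cp = ControlPoint(
        cumulative_mu_fraction=1.0,
        gantry_angle=0.0,
        bank_a_positions=bank_a,
        bank_b_positions=bank_b,
        jaw_x1=-gap / 2,
        jaw_x2=gap / 2,
        jaw_y1=-field_length / 2,
        jaw_y2=field_length / 2,
        nominal_time=0.0,
        dose_rate=0.0,
    )
    beam = Beam(
        control_points=[cp],
        total_mu=mu,
        technique="static-IMRT",
        machine=geom,
        arc_span=0.0,
        name="static",
    )
    return Plan(plan_id=plan_id, site_label="other", beams=[beam])


def make_sliding_window(
    gap: float,
    sweep: float,
    n_cp: int,
    field_length: float,
    mu: float,
    duration_s: float | None = None,
    arc_span: float = 0.0,
    geom: MachineGeometry | None = None,
    plan_id: str = "sliding-window",
) -> Plan:
    """Constant-gap window whose centre sweeps [-sweep/2, +sweep/2].

    All active pairs share identical trajectories with uniform MU fractions,
    so the interior exposure fraction is exactly gap/sweep — the fixture
    behind the closed-form offset law.
    """
    geom = geom or MachineGeometry()
    if n_cp < 2:
        raise ValueError("n_cp must be >= 2")
    if sweep <= gap:
        raise ValueError("sweep must exceed gap (no sweep otherwise)")
    if duration_s is None:
        duration_s = mu / 300.0 * 60.0  # 300 MU/min nominal
    inside = _field_pairs(geom, field_length)
    centers = np.linspace(-sweep / 2, sweep / 2, n_cp)
    jaw_x = sweep / 2 + gap / 2 + 5.0
    cps = []
    for k, c in enumerate(centers):
        frac = k / (n_cp - 1)
        bank_a = np.where(inside, c - gap / 2, 0.0)
        bank_b = np.where(inside, c + gap / 2, 0.0)
        gantry = -arc_span / 2 + frac * arc_span if arc_span else 0.0
        cps.append(
            ControlPoint(
                cumulative_mu_fraction=frac,
                gantry_angle=gantry,
                bank_a_positions=bank_a,
                bank_b_positions=bank_b,
                jaw_x1=-jaw_x,
                jaw_x2=jaw_x,
                jaw_y1=-field_length / 2,
                jaw_y2=field_length / 2,
                nominal_time=frac * duration_s,
                dose_rate=mu / duration_s * 60.0,
            )
        )
    beam = Beam(
        control_points=cps,
        total_mu=mu,
        technique="sliding-window",
        machine=geom,
        arc_span=arc_span,
        name="sweep",
    )
    return Plan(plan_id=plan_id, site_label="other", beams=[beam])
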