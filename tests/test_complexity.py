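"""complexity: hand-computed examples, oracle equivalence, invariances."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planperturb.complexity.metrics import (
    METRIC_NAMES,
    beam_metrics,
    compute_all,
    dynamics_metrics,
    edge_metric,
    gap_metrics,
    interdigitation_fraction,
    lt_per_al,
    mcs,
    modulation_index_total,
    plan_irregularity,
    plan_modulation,
    tgi,
)
from planperturb.machine_plan.types import Beam, ControlPoint, MachineGeometry, Plan
from planperturb.synthetic_cohort import generate_plan, make_sliding_window, make_static_field

from .conftest import small_presets
from .oracles import oracle_compute_all

GEOM = MachineGeometry()


def _cp(bank_a, bank_b, cmf=1.0, jaws=(-100, 100, -100, 100), t=0.0, dr=0.0, gantry=0.0):
    return ControlPoint(
        cumulative_mu_fraction=cmf,
        gantry_angle=gantry,
        bank_a_positions=np.asarray(bank_a, dtype=float),
        bank_b_positions=np.asarray(bank_b, dtype=float),
        jaw_x1=jaws[0],
        jaw_x2=jaws[1],
        jaw_y1=jaws[2],
        jaw_y2=jaws[3],
        nominal_time=t,
        dose_rate=dr,
    )


def _single_cp_beam(bank_a, bank_b, jaws=(-100, 100, -100, 100), mu=100.0):
    return Beam(
        control_points=[_cp(bank_a, bank_b, jaws=jaws)],
        total_mu=mu,
        technique="static-IMRT",
        machine=GEOM,
    )


def _pair_aperture(specs, jaws=(-100, 100, -100, 100)):
    """Beam with listed (pair_index, xa, xb); all other pairs closed."""
    bank_a = np.zeros(60)
    bank_b = np.zeros(60)
    for i, xa, xb in specs:
        bank_a[i] = xa
        bank_b[i] = xb
    return _single_cp_beam(bank_a, bank_b, jaws=jaws)


class TestGapMetrics:
    def test_uniform_rectangle(self, rect_plan):
        assert gap_metrics(rect_plan.beams[0]) == (30.0, 30.0)

    def test_two_segment_weighting(self):
        # static segments with MU fractions 0.25 / 0.75, uniform gaps 20 / 40
        inside = np.abs(GEOM.leaf_boundaries[:-1] + np.asarray(GEOM.leaf_widths) / 2) < 40
        cps = []
        for cmf, gap in ((0.25, 20.0), (1.0, 40.0)):
            bank_a = np.where(inside, -gap / 2, 0.0)
            bank_b = np.where(inside, gap / 2, 0.0)
            cps.append(_cp(bank_a, bank_b, cmf=cmf, jaws=(-50, 50, -40, 40)))
        beam = Beam(control_points=cps, total_mu=100, technique="static-IMRT", machine=GEOM)
        mean_gap, _ = gap_metrics(beam)
        assert mean_gap == pytest.approx(0.25 * 20 + 0.75 * 40)

    def test_no_active_pairs_undefined(self):
        beam = _single_cp_beam(np.zeros(60), np.zeros(60))
        mean_gap, q1 = gap_metrics(beam)
        assert math.isnan(mean_gap) and math.isnan(q1)


class TestTgi:
    def test_rectangle_zero(self, rect_plan):
        assert tgi(rect_plan.beams[0]) == 0.0

    def test_hand_example(self):
        # two adjacent pairs: A (-10, -15), B (10, 15); gaps 20 and 30
        beam = _pair_aperture([(29, -10.0, 10.0), (30, -15.0, 15.0)])
        # both banks: |diff| = 5, mean gap = 25 -> r = 0.2
        assert tgi(beam) == pytest.approx(0.2)

    def test_undefined_without_junction(self):
        beam = _pair_aperture([(30, -10.0, 10.0)])
        assert math.isnan(tgi(beam))


class TestMcs:
    def test_rectangle_is_one(self, rect_plan):
        assert mcs(rect_plan.beams[0]) == 1.0

    def test_bounded(self, seeded_small_plans):
        for plan in seeded_small_plans:
            for beam in plan.beams:
                assert 0.0 <= mcs(beam) <= 1.0


class TestPlanIrregularity:
    def test_single_rectangle_closed_form(self):
        # one open pair: 20 mm wide, 5 mm tall
        beam = _pair_aperture([(30, -10.0, 10.0)])
        w, h = 20.0, 5.0
        expected = (2 * (w + h)) ** 2 / (4 * math.pi * w * h)
        assert plan_irregularity(beam) == pytest.approx(expected, rel=1e-12)

    def test_circle_limit_from_above(self):
        # A leaf-step "circle" keeps its Manhattan perimeter (8r), so the
        # irregularity of rectilinear circle approximations tends to
        # 16 / pi^2 ~ 1.62 from below as rows shrink -- always above the
        # smooth-circle value of 1.
        radius = 40.0
        values = []
        for half_rows in (4, 8, 16):
            rows = []
            n = 2 * half_rows
            geom_widths = tuple([2 * radius / n] * n)
            geom = MachineGeometry(leaf_pair_count=n, leaf_widths=geom_widths)
            b = geom.leaf_boundaries
            bank_a, bank_b = np.zeros(n), np.zeros(n)
            for i in range(n):
                yc = (b[i] + b[i + 1]) / 2
                half = math.sqrt(max(radius**2 - yc**2, 0.0))
                bank_a[i], bank_b[i] = -half, half
            beam = Beam(
                control_points=[
                    ControlPoint(1.0, 0.0, bank_a, bank_b, -50, 50, -50, 50)
                ],
                total_mu=10,
                technique="static-IMRT",
                machine=geom,
            )
            values.append(plan_irregularity(beam))
        manhattan_limit = 16.0 / math.pi**2
        assert all(v > 1.0 for v in values)
        assert values[-1] == pytest.approx(manhattan_limit, rel=0.05)


class TestEdgeMetric:
    def test_rectangle_zero(self, rect_plan):
        assert edge_metric(rect_plan.beams[0]) == 0.0

    def test_offset_pair_hand_geometry(self):
        # two 5 mm pairs, 20 mm gaps, offset 5 mm -> edge 10 mm / 200 mm^2
        beam = _pair_aperture([(29, -10.0, 10.0), (30, -5.0, 15.0)])
        assert edge_metric(beam) == pytest.approx(10.0 / 200.0)


class TestPlanModulation:
    def test_static_zero(self, rect_plan):
        assert plan_modulation(rect_plan.beams[0]) == 0.0

    def test_two_disjoint_apertures(self):
        # equal-MU disjoint equal-area apertures -> PM = 0.5
        bank_a1 = np.zeros(60)
        bank_b1 = np.zeros(60)
        bank_a1[30], bank_b1[30] = -20.0, -10.0
        bank_a2 = np.zeros(60)
        bank_b2 = np.zeros(60)
        bank_a2[30], bank_b2[30] = 10.0, 20.0
        cps = [
            _cp(bank_a1, bank_b1, cmf=0.5),
            _cp(bank_a2, bank_b2, cmf=1.0),
        ]
        beam = Beam(control_points=cps, total_mu=100, technique="static-IMRT", machine=GEOM)
        assert plan_modulation(beam) == pytest.approx(0.5)

    def test_in_unit_interval(self, seeded_small_plans):
        for plan in seeded_small_plans:
            for beam in plan.beams:
                assert 0.0 <= plan_modulation(beam) < 1.0


class TestLeafTravel:
    def test_arc_normalized(self):
        plan = make_sliding_window(20, 80, 81, 100, 200, arc_span=360.0)
        assert lt_per_al(plan.beams[0]) == pytest.approx(80.0 / 360.0)

    def test_static_aperture_zero(self, rect_plan):
        assert lt_per_al(rect_plan.beams[0]) == 0.0

    def test_cp_refinement_invariance(self, sliding_plan):
        coarse = make_sliding_window(20, 80, 41, 100, 200, arc_span=358.0)
        fine = make_sliding_window(20, 80, 81, 100, 200, arc_span=358.0)
        assert lt_per_al(fine.beams[0]) == pytest.approx(
            lt_per_al(coarse.beams[0]), rel=1e-9
        )


class TestInterdigitation:
    def test_rectangle_zero(self, rect_plan):
        assert interdigitation_fraction(rect_plan.beams[0]) == 0.0

    def test_single_crossed_junction(self):
        # pair 30's bank A tip beyond pair 31's bank B tip
        beam = _pair_aperture([(30, 10.0, 30.0), (31, -30.0, 5.0)])
        assert interdigitation_fraction(beam) == pytest.approx(1.0 / 59.0)

    def test_bounded(self, seeded_small_plans):
        for plan in seeded_small_plans:
            for beam in plan.beams:
                assert 0.0 <= interdigitation_fraction(beam) <= 1.0


class TestDynamics:
    def test_constant_sweep_speed(self):
        plan = make_sliding_window(20, 80, 81, 100, 200, duration_s=40.0)
        out = dynamics_metrics(plan.beams[0])
        assert out["mean_mlc_speed"] == pytest.approx(2.0)
        assert out["mlc_speed_modulation"] == pytest.approx(0.0, abs=1e-9)

    def test_static_all_zero(self, rect_plan):
        out = dynamics_metrics(rect_plan.beams[0])
        assert all(v == 0.0 for v in out.values())


class TestModulationIndex:
    def test_constant_speed_zero(self):
        plan = make_sliding_window(20, 80, 41, 100, 200, duration_s=40.0)
        assert modulation_index_total(plan.beams[0]) == 0.0

    def test_alternating_changes_integral_one(self):
        # leaf speeds alternate so every change magnitude equals sigma
        n_cp = 9
        cps = []
        x = 0.0
        for k in range(n_cp):
            bank_a = np.full(60, -30.0)
            bank_b = np.full(60, -10.0)
            bank_a[28:32] = x - 10.0
            bank_b[28:32] = x + 10.0
            cps.append(
                _cp(
                    bank_a,
                    bank_b,
                    cmf=k / (n_cp - 1),
                    t=float(k),
                    jaws=(-100, 100, -10, 10),
                )
            )
            x += 4.0 if k % 2 == 0 else 1.0
        beam = Beam(control_points=cps, total_mu=100, technique="sliding-window", machine=GEOM)
        assert modulation_index_total(beam) == pytest.approx(1.0)

    def test_too_few_cps_undefined(self):
        cps = [
            _cp(np.full(60, -10.0), np.full(60, 10.0), cmf=0.0, t=0.0),
            _cp(np.full(60, -10.0), np.full(60, 10.0), cmf=1.0, t=1.0),
        ]
        beam = Beam(control_points=cps, total_mu=10, technique="sliding-window", machine=GEOM)
        assert math.isnan(modulation_index_total(beam))


class TestComputeAll:
    def test_single_beam_equals_beam_level(self, sliding_plan):
        mv = compute_all(sliding_plan)
        bm = beam_metrics(sliding_plan.beams[0])
        for name, value in bm.items():
            assert getattr(mv, name) == pytest.approx(value, rel=1e-12)

    def test_two_identical_beams_weighting_identity(self, sliding_plan):
        import copy

        double = Plan(
            plan_id="double",
            site_label="other",
            beams=[sliding_plan.beams[0], copy.deepcopy(sliding_plan.beams[0])],
        )
        mv1 = compute_all(sliding_plan)
        mv2 = compute_all(double)
        for name in METRIC_NAMES:
            if name == "total_mu":
                assert mv2.total_mu == pytest.approx(2 * mv1.total_mu)
            elif name == "n_arcs":
                continue
            else:
                assert getattr(mv2, name) == pytest.approx(
                    getattr(mv1, name), rel=1e-9
                ), name

    def test_mu_scale_property(self, seeded_small_plans):
        import copy

        plan = seeded_small_plans[0]
        scaled = copy.deepcopy(plan)
        for beam in scaled.beams:
            beam.total_mu *= 3.0
        mv, mv3 = compute_all(plan), compute_all(scaled)
        assert mv3.total_mu == pytest.approx(3 * mv.total_mu)
        for name in ("mean_gap", "q1_gap", "tgi", "mcs", "plan_modulation",
                     "edge_metric", "plan_irregularity", "lt_per_al",
                     "interdigitation_fraction", "n_arcs"):
            assert getattr(mv3, name) == pytest.approx(getattr(mv, name), rel=1e-9)


class TestRefinementInvariance:
    def test_interpolated_cp_insertion(self):
        coarse = make_sliding_window(24, 72, 25, 80, 150)
        fine = make_sliding_window(24, 72, 49, 80, 150)
        mc, mf = compute_all(coarse), compute_all(fine)
        for name in ("mean_gap", "tgi", "mcs"):
            c, f = getattr(mc, name), getattr(mf, name)
            if c == 0:
                assert abs(f) < 1e-9
            else:
                assert f == pytest.approx(c, rel=0.01)


class TestOracleEquivalence:
    def test_all_metrics_match_naive_loops(self, seeded_small_plans):
        for plan in seeded_small_plans:
            expected = oracle_compute_all(plan)
            actual = compute_all(plan).as_dict()
            for name in METRIC_NAMES:
                e, a = expected[name], actual[name]
                if math.isnan(e):
                    assert math.isnan(a), name
                elif name == "edge_metric":
                    assert a == pytest.approx(e, rel=0.02), (plan.plan_id, name)
                elif e == 0:
                    assert abs(a) < 1e-9, (plan.plan_id, name)
                else:
                    assert a == pytest.approx(e, rel=1e-9), (plan.plan_id, name)


@settings(max_examples=15, deadline=None)
@given(
    gap=st.floats(min_value=5.0, max_value=60.0),
    field=st.floats(min_value=20.0, max_value=150.0),
)
def test_property_rectangle_identities(gap, field):
    plan = make_static_field(gap, field, 100.0)
    mv = compute_all(plan)
    assert mv.mcs == 1.0
    assert mv.tgi == 0.0
    assert mv.plan_modulation == 0.0
    assert mv.edge_metric == 0.0
    assert mv.interdigitation_fraction == 0.0
    assert mv.mean_gap == pytest.approx(gap)
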