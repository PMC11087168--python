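"""fluence_surrogate: percentile seeding, pixel physics, deviations."""

from __future__ import annotations

import copy
import math

import numpy as np
import pytest

from planperturb.fluence_surrogate import (
    BeamModelParams,
    GridSpec,
    PercentileTable,
    RoiSet,
    accumulate_plan_map,
    control_point_fluence,
    default_percentile_table,
    dose_deviation,
    effective_leaf_positions,
    grid_for_plan,
    ideal_model,
    model_from_percentiles,
    rois_from_plan,
    table_from_yaml,
    table_to_yaml,
)
from planperturb.fluence_surrogate.deviation import roi_endpoints
from planperturb.machine_plan.types import Plan
from planperturb.synthetic_cohort import make_sliding_window, make_static_field

from .oracles import oracle_ols


class TestPercentileTable:
    def test_table_seeded_values(self, percentile_table):
        assert percentile_table.value("mlc_offset", 97.5) == 0.116
        assert percentile_table.value("mlc_transmission", 2.5) == 0.007
        assert percentile_table.value("leaf_tip_width", 50.0) == 0.320

    def test_model_overrides(self, percentile_table):
        model = model_from_percentiles(percentile_table, {"mlc_offset": 97.5})
        assert model.mlc_offset == 0.116
        assert model.mlc_transmission == 0.018  # stays at baseline

    def test_baseline_no_overrides(self, percentile_table):
        model = model_from_percentiles(percentile_table)
        assert model.mlc_offset == 0.040
        assert model.leaf_tip_width == 0.320

    def test_unknown_parameter_or_percentile(self, percentile_table):
        with pytest.raises(KeyError):
            model_from_percentiles(percentile_table, {"nope": 50.0})
        with pytest.raises(KeyError):
            model_from_percentiles(percentile_table, {"mlc_offset": 33.0})

    def test_non_monotone_rejected(self):
        rows = {"mlc_offset": {2.5: 0.1, 25.0: 0.0, 50.0: 0.2, 75.0: 0.3, 97.5: 0.4}}
        with pytest.raises(ValueError):
            PercentileTable(rows)

    def test_yaml_round_trip(self, tmp_path, percentile_table):
        path = tmp_path / "table.yaml"
        table_to_yaml(percentile_table, path)
        again = table_from_yaml(path)
        assert again.rows == percentile_table.rows


class TestEffectiveLeafPositions:
    def test_offset_only_grows_every_gap(self, sliding_plan):
        beam = sliding_plan.beams[0]
        cp = beam.control_points[10]
        model = BeamModelParams(mlc_offset=0.04)
        eff = effective_leaf_positions(cp, model)
        active = beam.active_pairs(cp)
        np.testing.assert_allclose(
            eff.gaps[active], cp.gaps[active] + 0.8, atol=1e-12
        )

    def test_gain_zero_at_axis(self):
        plan = make_static_field(0.5, 100, 10)  # tips essentially at x = 0
        cp = plan.beams[0].control_points[0]
        model = BeamModelParams(mlc_gain=0.5)
        eff = effective_leaf_positions(cp, model)
        # tip at x ~ 0.25 mm: gain shift = 0.5 * 0.025 cm / 10 -> ~0.01 mm
        np.testing.assert_allclose(eff.gaps, cp.gaps, atol=0.03)

    def test_curvature_quadratic(self):
        plan = make_static_field(100.0, 100, 10)  # bank B tips at x = +50 mm
        cp = plan.beams[0].control_points[0]
        model = BeamModelParams(mlc_curvature=0.01)
        eff = effective_leaf_positions(cp, model)
        active = plan.beams[0].active_pairs(cp)
        # 0.01 cm^-1 * (5 cm)^2 = 0.25 cm outward per tip
        np.testing.assert_allclose(
            eff.bank_b_positions[active], cp.bank_b_positions[active] + 2.5, atol=1e-9
        )

    def test_gap_never_negative(self, sliding_plan):
        cp = sliding_plan.beams[0].control_points[0]
        model = BeamModelParams(mlc_offset=-5.0)  # absurdly closing
        eff = effective_leaf_positions(cp, model)
        assert np.all(eff.gaps >= 0)


def _widened(plan: Plan, jaw_x: float = 60.0) -> Plan:
    out = copy.deepcopy(plan)
    for beam in out.beams:
        for cp in beam.control_points:
            cp.jaw_x1, cp.jaw_x2 = -jaw_x, jaw_x
    return out


class TestControlPointFluence:
    def test_open_and_blocked_values(self):
        plan = _widened(make_static_field(20, 50, 100))
        beam = plan.beams[0]
        model = BeamModelParams(mlc_transmission=0.018)
        grid = grid_for_plan(plan)
        fl = control_point_fluence(beam, beam.control_points[0], model, grid)
        ix_mid = np.argmin(np.abs(grid.x_centers))
        iy_mid = np.argmin(np.abs(grid.y_centers))
        assert fl.values[iy_mid, ix_mid] == 1.0
        ix_blocked = np.argmin(np.abs(grid.x_centers - 30.0))  # 20 mm behind tip
        assert fl.values[iy_mid, ix_blocked] == pytest.approx(0.018)

    def test_outside_jaws_zero(self):
        plan = make_static_field(20, 50, 100)
        beam = plan.beams[0]
        grid = grid_for_plan(plan)
        fl = control_point_fluence(beam, beam.control_points[0], ideal_model(), grid)
        iy_out = np.argmin(np.abs(grid.y_centers - 30.0))  # beyond jaw_y2 = 25
        assert np.all(fl.values[iy_out, :] == 0.0)

    def test_tip_band_excess_integral(self):
        # analytic: excess fluence per unit leaf-edge length = tw * (1 - T) / 2
        plan = _widened(make_static_field(20, 50, 100))
        beam = plan.beams[0]
        T, tw_cm = 0.018, 0.2
        grid = grid_for_plan(plan, GridSpec(resolution=0.25))
        sharp = control_point_fluence(
            beam, beam.control_points[0], BeamModelParams(mlc_transmission=T), grid
        )
        ramp = control_point_fluence(
            beam,
            beam.control_points[0],
            BeamModelParams(mlc_transmission=T, leaf_tip_width=tw_cm),
            grid,
        )
        excess = np.sum(ramp.values - sharp.values) * grid.resolution**2
        edge_length = 2 * 50.0  # both banks, 50 mm of open rows
        expected = edge_length * (tw_cm * 10.0) * (1 - T) / 2.0
        assert excess == pytest.approx(expected, rel=0.01)

    def test_undersampled_resolution_refused(self):
        plan = make_static_field(20, 50, 100)
        beam = plan.beams[0]
        grid = grid_for_plan(plan, GridSpec(resolution=2.0))
        model = BeamModelParams(leaf_tip_width=0.177)
        with pytest.raises(ValueError):
            control_point_fluence(beam, beam.control_points[0], model, grid)


class TestAccumulate:
    def test_two_identical_beams_equal_one(self, sliding_plan):
        double = Plan(
            plan_id="d",
            site_label="other",
            beams=[sliding_plan.beams[0], copy.deepcopy(sliding_plan.beams[0])],
        )
        m1 = accumulate_plan_map(sliding_plan, ideal_model())
        m2 = accumulate_plan_map(double, ideal_model())
        np.testing.assert_allclose(m2.values, m1.values, atol=1e-12)

    def test_zero_weight_cp_contributes_nothing(self, sliding_plan):
        # degenerate: repeat first CP with zero MU increment
        plan = copy.deepcopy(sliding_plan)
        beam = plan.beams[0]
        clone = beam.control_points[0].copy()
        beam.control_points.insert(0, clone)
        m1 = accumulate_plan_map(sliding_plan, ideal_model())
        m2 = accumulate_plan_map(plan, ideal_model())
        np.testing.assert_allclose(m2.values, m1.values, atol=1e-9)

    def test_sliding_plateau_uniform(self, sliding_plan):
        fl = accumulate_plan_map(sliding_plan, ideal_model())
        x, y = fl.x_centers, fl.y_centers
        interior = (np.abs(x)[None, :] <= 25.0) & (np.abs(y)[:, None] <= 40.0)
        vals = fl.values[interior]
        assert np.std(vals) / np.mean(vals) < 0.005

    def test_blur_preserves_integral(self, sliding_plan):
        m0 = accumulate_plan_map(sliding_plan, ideal_model())
        m1 = accumulate_plan_map(sliding_plan, BeamModelParams(source_sigma=0.2))
        assert np.sum(m1.values) == pytest.approx(np.sum(m0.values), rel=0.005)


class TestRoiEndpoints:
    def _uniform_grid_rois(self, v=0.7, n=40):
        from planperturb.fluence_surrogate.fluence import FluenceGrid

        values = np.full((n, n), v)
        grid = FluenceGrid(values, 1.0, -n / 2, -n / 2)
        mask = np.zeros((n, n), dtype=bool)
        mask[10:30, 10:30] = True
        rois = RoiSet(ctv=mask, oar_parallel=mask, oar_serial=mask)
        return grid, rois

    def test_uniform_map(self):
        grid, rois = self._uniform_grid_rois(v=0.7)
        eps = roi_endpoints(grid, rois, baseline=grid)
        for name in ("ctv_mean", "oar_mean", "oar_near_max", "ctv_min", "ctv_max", "ctv_d95"):
            assert eps[name] == pytest.approx(0.7)
        assert eps["coverage"] == 1.0

    def test_near_max_percentile(self):
        from planperturb.fluence_surrogate.fluence import FluenceGrid

        values = np.ones((40, 25))  # 1000 pixels
        flat = values.reshape(-1)
        flat[:20] = 2.0  # 20 of 1000 pixels at 2v
        grid = FluenceGrid(values, 1.0, 0.0, 0.0)
        mask = np.ones((40, 25), dtype=bool)
        rois = RoiSet(ctv=mask, oar_parallel=mask, oar_serial=mask)
        eps = roi_endpoints(grid, rois)
        assert eps["oar_near_max"] == pytest.approx(2.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            RoiSet(
                ctv=np.zeros((4, 4), dtype=bool),
                oar_parallel=np.ones((4, 4), dtype=bool),
                oar_serial=np.ones((4, 4), dtype=bool),
            )


class TestDoseDeviation:
    def test_zero_perturbation_identity(self, sliding_plan, percentile_table):
        baseline = model_from_percentiles(percentile_table)
        devs = dose_deviation(sliding_plan, baseline, baseline)
        assert all(v == 0.0 for v in devs.values())

    @pytest.mark.parametrize("gap", [10.0, 20.0, 30.0, 40.0])
    def test_offset_law(self, gap):
        plan = make_sliding_window(gap, 80, 81, 100, 200)
        base = ideal_model()
        pert = base.replace(mlc_offset=0.076)
        dev = dose_deviation(plan, pert, base)
        assert dev["ctv_mean"] == pytest.approx(2 * 0.76 / gap * 100.0, rel=0.02)

    def test_transmission_on_blocked_roi(self):
        plan = _widened(make_static_field(20, 50, 100))
        grid = grid_for_plan(plan)
        x, y = grid.x_centers, grid.y_centers
        blocked = (
            (x[None, :] >= 25.0)
            & (x[None, :] <= 45.0)
            & (np.abs(y[:, None]) <= 20.0)
        )
        ctv = (np.abs(x)[None, :] <= 8.0) & (np.abs(y[:, None]) <= 20.0)
        rois = RoiSet(ctv=ctv, oar_parallel=blocked, oar_serial=blocked)
        base = BeamModelParams(mlc_transmission=0.018)
        pert = BeamModelParams(mlc_transmission=0.025)
        dev = dose_deviation(plan, pert, base, rois=rois)
        assert dev["oar_mean"] == pytest.approx(100 * (0.025 - 0.018) / 0.018, rel=1e-9)

    def test_transmission_linearity_on_blocked_roi(self):
        plan = _widened(make_static_field(20, 50, 100))
        grid = grid_for_plan(plan)
        x, y = grid.x_centers, grid.y_centers
        blocked = (
            (x[None, :] >= 25.0)
            & (x[None, :] <= 45.0)
            & (np.abs(y[:, None]) <= 20.0)
        )
        ctv = (np.abs(x)[None, :] <= 8.0) & (np.abs(y[:, None]) <= 20.0)
        rois = RoiSet(ctv=ctv, oar_parallel=blocked, oar_serial=blocked)
        base = BeamModelParams(mlc_transmission=0.018)
        ts = [0.007, 0.015, 0.022, 0.025]
        devs = [
            dose_deviation(plan, BeamModelParams(mlc_transmission=t), base, rois=rois)[
                "oar_mean"
            ]
            for t in ts
        ]
        _, _, r2 = oracle_ols(ts, devs)
        assert r2 > 0.999

    def test_direction_consistency(self, percentile_table):
        plan = make_sliding_window(18, 70, 41, 80, 200)
        base = model_from_percentiles(percentile_table)
        for param in ("mlc_offset", "mlc_transmission"):
            hi = model_from_percentiles(percentile_table, {param: 97.5})
            lo = model_from_percentiles(percentile_table, {param: 2.5})
            assert dose_deviation(plan, hi, base)["ctv_mean"] > 0
            assert dose_deviation(plan, lo, base)["ctv_mean"] < 0


class TestRoisFromPlan:
    def test_ctv_inside_sweep_interior(self, sliding_plan):
        grid = grid_for_plan(sliding_plan)
        rois = rois_from_plan(sliding_plan, grid=grid)
        x, y = np.meshgrid(grid.x_centers, grid.y_centers)
        assert np.all(np.abs(x[rois.ctv]) <= 30.0 + 1e-9)
        assert np.all(np.abs(y[rois.ctv]) <= 50.0 + 1e-9)
        assert not np.any(rois.ctv & rois.oar_serial)

    def test_site_depths(self, default_cohort):
        plan = next(p for p in default_cohort if p.site_label == "prostate")
        rois = rois_from_plan(plan)
        assert rois.depths["ctv"] == 17.0
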