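"""Shared fixtures: analytic fixtures, seeded small plans, the default cohort."""

from __future__ import annotations

import pytest

from planperturb.complexity.metrics import compute_all
from planperturb.fluence_surrogate.params import default_percentile_table
from planperturb.synthetic_cohort.fixtures import make_sliding_window, make_static_field
from planperturb.synthetic_cohort.generator import generate_cohort, generate_plan
from planperturb.synthetic_cohort.presets import CohortSpec, SitePreset, default_presets


@pytest.fixture
def rect_plan():
    return make_static_field(gap=30.0, field_length=100.0, mu=100.0)


@pytest.fixture
def sliding_plan():
    return make_sliding_window(gap=20.0, sweep=80.0, n_cp=81, field_length=100.0, mu=200.0)


def small_presets():
    """Down-scaled presets (<= 50 CPs) for oracle and property tests."""
    out = []
    for preset in default_presets():
        out.append(
            SitePreset(
                site_label=preset.site_label,
                n_beams=1,
                cp_count=min(preset.cp_count, 30),
                target_mean_gap_range=preset.target_mean_gap_range,
                target_tgi_range=preset.target_tgi_range,
                sweep_extent=preset.sweep_extent,
                mu_range=preset.mu_range,
                adjacency_roughness=preset.adjacency_roughness,
                gap_dispersion=preset.gap_dispersion,
                field_length=preset.field_length,
                technique=preset.technique,
                arc_span=preset.arc_span,
            )
        )
    return out


@pytest.fixture(scope="session")
def seeded_small_plans():
    """Ten seeded plans (<= 50 CPs, mixed techniques) for oracle equivalence."""
    presets = small_presets()
    plans = []
    for seed in range(10):
        preset = presets[seed % len(presets)]
        plans.append(generate_plan(preset, seed=(1234, seed), plan_id=f"small-{seed}"))
    return plans


@pytest.fixture(scope="session")
def default_cohort():
    """The default 25-plan cohort at master seed 0."""
    return generate_cohort(CohortSpec(master_seed=0))


@pytest.fixture(scope="session")
def cohort_metrics(default_cohort):
    return {plan.plan_id: compute_all(plan) for plan in default_cohort}


@pytest.fixture(scope="session")
def percentile_table():
    return default_percentile_table()


@pytest.fixture(scope="session")
def cohort_records(default_cohort, percentile_table):
    """Deviation records for the three headline parameters, all percentiles.

    Shared across acceptance tests (grid structure, sign/ordering, ranking)
    because the fluence grid dominates suite runtime.
    """
    from planperturb.study.grid import run_grid

    return run_grid(
        default_cohort,
        percentile_table,
        parameters=["mlc_offset", "mlc_transmission", "leaf_tip_width"],
    )
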