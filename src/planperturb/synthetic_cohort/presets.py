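"""Site presets and cohort specification.

Preset target ranges are invented study knobs, chosen so that the cohort's
complexity ordering is head-and-neck ~ mesothelioma (most complex / smallest
mean gap) < prostate < brain ~ lung, and so the generated mean-gap spectrum
brackets the decision thresholds exercised by the threshold-derivation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import yaml


@dataclass
class SitePreset:
    site_label: str
    n_beams: int = 2
    cp_count: int = 72
    target_mean_gap_range: Tuple[float, float] = (15.0, 30.0)  # mm
    target_tgi_range: Tuple[float, float] = (0.05, 0.6)
    sweep_extent: float = 80.0  # mm
    mu_range: Tuple[float, float] = (300.0, 700.0)
    adjacency_roughness: float = 0.5
    gap_dispersion: float = 0.25
    field_length: float = 80.0  # mm along the leaf-pair axis
    technique: str = "VMAT-arc"
    arc_span: float = 358.0

    def __post_init__(self) -> None:
        lo, hi = self.target_mean_gap_range
        if lo <= 0 or hi < lo:
            raise ValueError("target_mean_gap_range must be positive and ordered")
        tlo, thi = self.target_tgi_range
        if not (0.0 <= tlo <= thi < 1.0):
            raise ValueError("target_tgi_range must lie within [0, 1)")
        if self.sweep_extent <= 0 or self.field_length <= 0:
            raise ValueError("geometry extents must be positive")


def default_presets() -> List[SitePreset]:
    return [
        SitePreset(
            site_label="head_and_neck",
            target_mean_gap_range=(10.0, 20.0),
            target_tgi_range=(0.18, 0.38),
            adjacency_roughness=0.9,
            sweep_extent=70.0,
            field_length=100.0,
            cp_count=72,
            n_beams=2,
        ),
        SitePreset(
            site_label="mesothelioma",
            target_mean_gap_range=(12.0, 22.0),
            target_tgi_range=(0.16, 0.34),
            adjacency_roughness=0.8,
            sweep_extent=80.0,
            field_length=120.0,
            cp_count=24,
            n_beams=4,
            technique="static-IMRT",
            arc_span=0.0,
        ),
        SitePreset(
            site_label="prostate",
            target_mean_gap_range=(18.0, 32.0),
            target_tgi_range=(0.10, 0.24),
            adjacency_roughness=0.5,
            sweep_extent=75.0,
            field_length=60.0,
            cp_count=72,
            n_beams=2,
        ),
        SitePreset(
            site_label="brain",
            target_mean_gap_range=(25.0, 42.0),
            target_tgi_range=(0.06, 0.18),
            adjacency_roughness=0.3,
            sweep_extent=85.0,
            field_length=60.0,
            cp_count=72,
            n_beams=1,
        ),
        SitePreset(
            site_label="lung",
            target_mean_gap_range=(25.0, 48.0),
            target_tgi_range=(0.04, 0.12),
            adjacency_roughness=0.2,
            sweep_extent=90.0,
            field_length=80.0,
            cp_count=72,
            n_beams=1,
        ),
    ]


@dataclass
class CohortSpec:
    plans_per_site: int = 5
    sites: List[SitePreset] = field(default_factory=default_presets)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.plans_per_site < 1:
            raise ValueError("plans_per_site must be >= 1")


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from YAML; omitted preset fields keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sites_data = data.get("sites")
    sites = (
        [SitePreset(**sd) for sd in sites_data] if sites_data else default_presets()
    )
    return CohortSpec(
        plans_per_site=data.get("plans_per_site", 5),
        sites=sites,
        master_seed=data.get("master_seed", 0),
    )


def spec_to_yaml(spec: CohortSpec, path) -> str:
    data = {
        "plans_per_site": spec.plans_per_site,
        "master_seed": spec.master_seed,
        "sites": [
            {
                "site_label": p.site_label,
                "n_beams": p.n_beams,
                "cp_count": p.cp_count,
                "target_mean_gap_range": list(p.target_mean_gap_range),
                "target_tgi_range": list(p.target_tgi_range),
                "sweep_extent": p.sweep_extent,
                "mu_range": list(p.mu_range),
                "adjacency_roughness": p.adjacency_roughness,
                "gap_dispersion": p.gap_dispersion,
                "field_length": p.field_length,
                "technique": p.technique,
                "arc_span": p.arc_span,
            }
            for p in spec.sites
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return str(path)
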