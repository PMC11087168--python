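"""Beam-model parameters and the community percentile table.

The offset, transmission and leaf-tip-width rows of the default table are
seeded from published community data.  The transmission row is labelled in
percent in that source but its values (0.007-0.025) are read as fractions
(0.7 %-2.5 %), the physically plausible interpretation.  All other rows are
PLACEHOLDER values: monotone, plausible spreads with no community-data
citation; replace them (YAML) before drawing quantitative conclusions about
those parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace
from typing import Dict, Mapping

import yaml

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)

PARAMETER_NAMES = [
    "mlc_offset",
    "mlc_gain",
    "mlc_curvature",
    "mlc_transmission",
    "leaf_tip_width",
    "tg_width",
    "source_sigma",
    "pdd_slope_err",
    "output_factor_err",
    "off_axis_err",
]


@dataclass(frozen=True)
class BeamModelParams:
    """The ten perturbable treatment-planning-system beam-model parameters."""

    mlc_offset: float = 0.0  # cm, positive opens each bank outward
    mlc_gain: float = 0.0  # dimensionless, scales with |x|/10 cm
    mlc_curvature: float = 0.0  # 1/cm, second-order offset correction
    mlc_transmission: float = 0.0  # fraction under the leaves
    leaf_tip_width: float = 0.0  # cm, rounded-tip ramp width
    tg_width: float = 0.0  # cm, tongue-and-groove strip width
    source_sigma: float = 0.0  # cm, Gaussian source blur at isocenter
    pdd_slope_err: float = 0.0  # fraction per cm depth (relative to 10 cm)
    output_factor_err: float = 0.0  # fraction per unit equivalent-square term
    off_axis_err: float = 0.0  # fraction at 10 cm off-axis radius

    def __post_init__(self) -> None:
        if not (0.0 <= self.mlc_transmission < 1.0):
            raise ValueError("mlc_transmission must lie in [0, 1)")
        if self.leaf_tip_width < 0 or self.source_sigma < 0 or self.tg_width < 0:
            raise ValueError("widths and source sigma must be >= 0")

    def replace(self, **kwargs) -> "BeamModelParams":
        return replace(self, **kwargs)


# Table-seeded rows (exact) + PLACEHOLDER rows (see module docstring).
_DEFAULT_TABLE: Dict[str, Dict[float, float]] = {
    "mlc_offset": {2.5: 0.000, 25.0: 0.017, 50.0: 0.040, 75.0: 0.055, 97.5: 0.116},
    "mlc_transmission": {2.5: 0.007, 25.0: 0.015, 50.0: 0.018, 75.0: 0.022, 97.5: 0.025},
    "leaf_tip_width": {2.5: 0.177, 25.0: 0.200, 50.0: 0.320, 75.0: 0.400, 97.5: 0.500},
    # PLACEHOLDER rows below
    "mlc_gain": {2.5: -0.010, 25.0: -0.003, 50.0: 0.000, 75.0: 0.003, 97.5: 0.010},
    "mlc_curvature": {2.5: -0.0020, 25.0: -0.0005, 50.0: 0.0000, 75.0: 0.0005, 97.5: 0.0020},
    "tg_width": {2.5: 0.00, 25.0: 0.02, 50.0: 0.05, 75.0: 0.08, 97.5: 0.12},
    "source_sigma": {2.5: 0.05, 25.0: 0.10, 50.0: 0.15, 75.0: 0.20, 97.5: 0.30},
    "pdd_slope_err": {2.5: -0.004, 25.0: -0.001, 50.0: 0.000, 75.0: 0.001, 97.5: 0.004},
    "output_factor_err": {2.5: -0.020, 25.0: -0.005, 50.0: 0.000, 75.0: 0.005, 97.5: 0.020},
    "off_axis_err": {2.5: -0.020, 25.0: -0.005, 50.0: 0.000, 75.0: 0.005, 97.5: 0.020},
}


@dataclass
class PercentileTable:
    """Per-parameter values at the 2.5/25/50/75/97.5 community percentiles."""

    rows: Dict[str, Dict[float, float]]

    def __post_init__(self) -> None:
        for name, row in self.rows.items():
            if name not in PARAMETER_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            missing = set(PERCENTILES) - set(row)
            if missing:
                raise ValueError(f"{name}: missing percentiles {sorted(missing)}")
            values = [row[p] for p in PERCENTILES]
            if any(b < a for a, b in zip(values, values[1:])):
                raise ValueError(f"{name}: values must be monotone across percentiles")

    def value(self, parameter: str, percentile: float) -> float:
        if parameter not in self.rows:
            raise KeyError(f"unknown parameter {parameter!r}")
        if percentile not in self.rows[parameter]:
            raise KeyError(f"unknown percentile {percentile!r}")
        return self.rows[parameter][percentile]

    @property
    def parameters(self):
        return list(self.rows)


def default_percentile_table() -> PercentileTable:
    return PercentileTable({k: dict(v) for k, v in _DEFAULT_TABLE.items()})


def table_from_yaml(path) -> PercentileTable:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rows = {
        name: {float(p): float(v) for p, v in row.items()}
        for name, row in data.items()
    }
    return PercentileTable(rows)


def table_to_yaml(table: PercentileTable, path) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {name: {p: row[p] for p in PERCENTILES} for name, row in table.rows.items()},
            fh,
            sort_keys=False,
        )
    return str(path)


def model_from_percentiles(
    table: PercentileTable, overrides: Mapping[str, float] | None = None
) -> BeamModelParams:
    """Build a model at the 50th-percentile baseline, with per-parameter overrides.

    ``overrides`` maps parameter name -> percentile level (one of 2.5, 25,
    50, 75, 97.5).  Unknown names or levels raise ``KeyError``.
    """
    values = {name: table.value(name, 50.0) for name in table.parameters}
    for name in PARAMETER_NAMES:
        values.setdefault(name, 0.0)
    if overrides:
        for name, pct in overrides.items():
            values[name] = table.value(name, float(pct))
    return BeamModelParams(**values)


def ideal_model(transmission: float = 0.0) -> BeamModelParams:
    """A pristine model (all parameters zero) used by analytic fixtures."""
    return BeamModelParams(mlc_transmission=transmission)
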