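"""Study configuration (versioned YAML schema, one master seed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from ..fluence_surrogate.params import PercentileTable, default_percentile_table, table_from_yaml
from ..study.grid import STUDY_PERCENTILES
from ..synthetic_cohort.presets import CohortSpec, spec_from_yaml

CONFIG_VERSION = 1


@dataclass
class StudyConfig:
    out_dir: Path = Path("results")
    cohort_spec_path: Optional[Path] = None  # None -> built-in default presets
    percentile_table_path: Optional[Path] = None  # None -> built-in table
    parameters: Optional[List[str]] = None  # None -> all ten
    percentiles: Sequence[float] = STUDY_PERCENTILES
    resolution: float = 0.5  # mm/pixel
    binary_fluence: bool = False  # force source_sigma = tg_width = 0
    master_seed: int = 0
    dev_threshold: float = 1.0  # % for the parameter filter
    contribution_threshold: float = 0.10
    include_pdd: bool = False  # include pdd_slope_err in metric regressions
    dose_limits: Sequence[float] = (2.0, 4.0)  # % thresholds to derive

    def cohort_spec(self) -> CohortSpec:
        if self.cohort_spec_path is not None:
            spec = spec_from_yaml(self.cohort_spec_path)
        else:
            spec = CohortSpec()
        spec.master_seed = self.master_seed
        return spec

    def percentile_table(self) -> PercentileTable:
        if self.percentile_table_path is not None:
            return table_from_yaml(self.percentile_table_path)
        return default_percentile_table()


def config_from_yaml(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    version = data.pop("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {version}")
    base = Path(path).parent
    cfg = StudyConfig()
    for key in (
        "parameters",
        "percentiles",
        "resolution",
        "binary_fluence",
        "master_seed",
        "dev_threshold",
        "contribution_threshold",
        "include_pdd",
        "dose_limits",
    ):
        if key in data:
            setattr(cfg, key, data[key])
    if data.get("out_dir"):
        cfg.out_dir = Path(data["out_dir"])
    for key, attr in (
        ("cohort_spec", "cohort_spec_path"),
        ("percentile_table", "percentile_table_path"),
    ):
        if data.get(key):
            p = Path(data[key])
            setattr(cfg, attr, p if p.is_absolute() else base / p)
    return cfg
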