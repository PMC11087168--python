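"""Domain model: machine geometry, control points, beams and plans.

Coordinate conventions
----------------------
Leaf-tip x positions are in millimetres at the isocenter plane.  Bank A is
the left (negative-travel) bank and bank B the right bank, so the leaf-pair
gap is ``bank_b - bank_a`` and must be non-negative.  The leaf-pair axis
(y) is described by 61 cumulative leaf boundaries, symmetric about zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np

Technique = Literal["static-IMRT", "sliding-window", "VMAT-arc"]

SITE_LABELS = ("prostate", "lung", "head_and_neck", "brain", "mesothelioma", "other")


@dataclass(frozen=True)
class MachineGeometry:
    """120-leaf (60 pair) MLC geometry of a Varian Millennium-style machine.

    10 outer pairs of 10 mm, 40 central pairs of 5 mm, 10 outer pairs of
    10 mm, for a 400 mm leaf-bank span symmetric about the beam axis.
    """

    leaf_pair_count: int = 60
    leaf_widths: tuple = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
    max_leaf_position: float = 200.0
    min_dynamic_gap: float = 0.6

    @property
    def leaf_boundaries(self) -> np.ndarray:
        """61 cumulative y-positions (mm), strictly increasing, symmetric about 0."""
        edges = np.concatenate([[0.0], np.cumsum(self.leaf_widths)])
        return edges - edges[-1] / 2.0

    def __post_init__(self) -> None:
        if len(self.leaf_widths) != self.leaf_pair_count:
            raise ValueError("leaf_widths length must equal leaf_pair_count")
        b = self.leaf_boundaries
        if not np.all(np.diff(b) > 0):
            raise ValueError("leaf boundaries must be strictly increasing")
        if not math.isclose(float(b[-1] - b[0]), sum(self.leaf_widths)):
            raise ValueError("boundary span must equal sum of leaf widths")
        if not math.isclose(float(b[0] + b[-1]), 0.0, abs_tol=1e-9):
            raise ValueError("boundaries must be symmetric about 0")


@dataclass
class ControlPoint:
    """One machine-state snapshot of a dynamic delivery."""

    cumulative_mu_fraction: float
    gantry_angle: float
    bank_a_positions: np.ndarray  # mm, left bank tips
    bank_b_positions: np.ndarray  # mm, right bank tips
    jaw_x1: float
    jaw_x2: float
    jaw_y1: float
    jaw_y2: float
    nominal_time: float = 0.0  # s from beam start
    dose_rate: float = 0.0  # MU/min

    def __post_init__(self) -> None:
        self.bank_a_positions = np.asarray(self.bank_a_positions, dtype=float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, dtype=float)

    @property
    def gaps(self) -> np.ndarray:
        return self.bank_b_positions - self.bank_a_positions

    def copy(self) -> "ControlPoint":
        return ControlPoint(
            cumulative_mu_fraction=self.cumulative_mu_fraction,
            gantry_angle=self.gantry_angle,
            bank_a_positions=self.bank_a_positions.copy(),
            bank_b_positions=self.bank_b_positions.copy(),
            jaw_x1=self.jaw_x1,
            jaw_x2=self.jaw_x2,
            jaw_y1=self.jaw_y1,
            jaw_y2=self.jaw_y2,
            nominal_time=self.nominal_time,
            dose_rate=self.dose_rate,
        )


@dataclass
class Beam:
    control_points: List[ControlPoint]
    total_mu: float
    technique: Technique = "VMAT-arc"
    machine: MachineGeometry = field(default_factory=MachineGeometry)
    arc_span: float = 0.0  # deg, 0 for static gantry
    name: str = ""

    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    def mu_weights(self) -> np.ndarray:
        """Per-control-point MU-fraction weights.

        Static-IMRT beams treat every control point as a segment whose
        weight is its cumulative-meterset increment (the first segment's
        increment is counted from zero).  Dynamic beams attribute each
        meterset increment half to the opening and half to the closing
        control point of the interval.
        """
        cmf = np.array([cp.cumulative_mu_fraction for cp in self.control_points])
        if len(cmf) == 1:
            return np.array([1.0])
        if self.technique == "static-IMRT":
            return np.diff(np.concatenate([[0.0], cmf]))
        inc = np.diff(cmf)
        w = np.zeros_like(cmf)
        w[:-1] += inc / 2.0
        w[1:] += inc / 2.0
        return w

    def active_pairs(self, cp: ControlPoint) -> np.ndarray:
        """Boolean mask of leaf pairs considered open at ``cp``.

        A pair is active iff its gap exceeds the machine's minimum dynamic
        gap and its y-extent overlaps the open jaw window.
        """
        b = self.machine.leaf_boundaries
        gap_open = cp.gaps > self.machine.min_dynamic_gap
        y_overlap = (b[1:] > cp.jaw_y1) & (b[:-1] < cp.jaw_y2)
        return gap_open & y_overlap


@dataclass
class Plan:
    plan_id: str
    site_label: str
    beams: List[Beam]
    rois: Optional[object] = None  # RoiSet, attached by the surrogate layer

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))

    @property
    def n_arcs(self) -> int:
        return sum(1 for b in self.beams if b.technique == "VMAT-arc")


def validate_plan(plan: Plan) -> List[str]:
    """Check type invariants; return human-readable violation descriptors.

    Reports rather than throws: an empty list means the plan is valid.
    """
    violations: List[str] = []
    if not plan.beams:
        violations.append("plan has no beams")
    if plan.site_label not in SITE_LABELS:
        violations.append(f"unknown site_label {plan.site_label!r}")
    for bi, beam in enumerate(plan.beams):
        if beam.total_mu <= 0:
            violations.append(f"beam {bi}: total_mu must be > 0")
        if beam.technique != "static-IMRT" and beam.n_cp < 2:
            violations.append(f"beam {bi}: dynamic technique needs >= 2 control points")
        n = beam.machine.leaf_pair_count
        prev_cmf = -np.inf
        prev_t = -np.inf
        for ci, cp in enumerate(beam.control_points):
            if len(cp.bank_a_positions) != n or len(cp.bank_b_positions) != n:
                violations.append(f"beam {bi} CP {ci}: leaf count != {n}")
                continue
            gaps = cp.gaps
            bad = np.nonzero(gaps < -1e-9)[0]
            for pair in bad:
                violations.append(
                    f"beam {bi} CP {ci}: bank A crosses bank B on pair {int(pair)}"
                )
            if cp.cumulative_mu_fraction < prev_cmf - 1e-12:
                violations.append(
                    f"beam {bi} CP {ci}: decreasing cumulative MU fraction"
                )
            if cp.nominal_time < prev_t - 1e-9:
                violations.append(f"beam {bi} CP {ci}: decreasing nominal_time")
            over = np.max(
                np.abs(np.concatenate([cp.bank_a_positions, cp.bank_b_positions]))
            )
            if over > beam.machine.max_leaf_position + 1e-9:
                violations.append(
                    f"beam {bi} CP {ci}: leaf position beyond max travel "
                    f"({over:.2f} mm)"
                )
            prev_cmf = cp.cumulative_mu_fraction
            prev_t = cp.nominal_time
        if beam.n_cp >= 2:
            first = beam.control_points[0].cumulative_mu_fraction
            last = beam.control_points[-1].cumulative_mu_fraction
            if beam.technique != "static-IMRT" and abs(first) > 1e-9:
                violations.append(f"beam {bi}: first cumulative MU fraction != 0")
            if abs(last - 1.0) > 1e-9:
                violations.append(f"beam {bi}: last cumulative MU fraction != 1")
    return violations
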