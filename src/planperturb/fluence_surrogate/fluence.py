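"""2D beam's-eye-view aperture-fluence surrogate.

Pixel physics, in order: leaf-pair transmission/tip-ramp profile, effective
leaf positions shifted outward by offset/gain/curvature, tongue-and-groove
strips at junction edges, jaw clipping (jaw transmission is ignored), a
single Gaussian source blur of the accumulated map, and multiplicative
off-axis / output-factor modifiers.  The blur and scalar modifiers are
linear, so the plan map convolves the MU-weighted control-point sum once
rather than every control point; the two routes are mathematically equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from ..machine_plan.types import Beam, ControlPoint, MachineGeometry, Plan
from .params import BeamModelParams

L_REF_CM = 10.0  # reference off-axis distance for the gain term


@dataclass
class GridSpec:
    resolution: float = 0.5  # mm per pixel
    margin: float = 12.0  # mm beyond the jaw window


@dataclass
class FluenceGrid:
    values: np.ndarray  # (ny, nx), dimensionless dose proxy
    resolution: float
    x_min: float
    y_min: float

    @property
    def x_centers(self) -> np.ndarray:
        nx = self.values.shape[1]
        return self.x_min + (np.arange(nx) + 0.5) * self.resolution

    @property
    def y_centers(self) -> np.ndarray:
        ny = self.values.shape[0]
        return self.y_min + (np.arange(ny) + 0.5) * self.resolution

    def like(self, values: np.ndarray) -> "FluenceGrid":
        return FluenceGrid(values, self.resolution, self.x_min, self.y_min)


def grid_for_plan(plan: Plan, spec: GridSpec | None = None) -> FluenceGrid:
    """Empty grid covering every beam's jaw window plus the margin."""
    spec = spec or GridSpec()
    x1 = min(cp.jaw_x1 for b in plan.beams for cp in b.control_points)
    x2 = max(cp.jaw_x2 for b in plan.beams for cp in b.control_points)
    y1 = min(cp.jaw_y1 for b in plan.beams for cp in b.control_points)
    y2 = max(cp.jaw_y2 for b in plan.beams for cp in b.control_points)
    res = spec.resolution
    x_min = x1 - spec.margin
    y_min = y1 - spec.margin
    nx = int(np.ceil((x2 + spec.margin - x_min) / res))
    ny = int(np.ceil((y2 + spec.margin - y_min) / res))
    return FluenceGrid(np.zeros((ny, nx)), res, x_min, y_min)


def effective_leaf_positions(
    cp: ControlPoint, model: BeamModelParams, geom: MachineGeometry | None = None
) -> ControlPoint:
    """Shift each bank tip outward by offset + gain.|x|/10cm + curvature.x^2.

    The shift is evaluated at the tip's own x (cm); a net-negative shift may
    close the aperture, in which case both tips collapse to their midpoint
    so the gap never goes below zero.
    """
    out = cp.copy()

    def delta_mm(x_mm: np.ndarray) -> np.ndarray:
        x_cm = x_mm / 10.0
        return 10.0 * (
            model.mlc_offset
            + model.mlc_gain * np.abs(x_cm) / L_REF_CM
            + model.mlc_curvature * x_cm**2
        )

    xa = cp.bank_a_positions - delta_mm(cp.bank_a_positions)
    xb = cp.bank_b_positions + delta_mm(cp.bank_b_positions)
    crossed = xb < xa
    mid = (xa + xb) / 2.0
    out.bank_a_positions = np.where(crossed, mid, xa)
    out.bank_b_positions = np.where(crossed, mid, xb)
    return out


def _row_pair_index(geom: MachineGeometry, y: np.ndarray) -> np.ndarray:
    """Leaf-pair index per y pixel row, -1 outside the leaf bank."""
    b = geom.leaf_boundaries
    idx = np.searchsorted(b, y, side="right") - 1
    idx[(y < b[0]) | (y >= b[-1])] = -1
    return np.clip(idx, -1, geom.leaf_pair_count - 1)


def _cp_fluence_raw(
    beam: Beam, cp: ControlPoint, model: BeamModelParams, grid: FluenceGrid
) -> np.ndarray:
    """Unblurred fluence for one control point (jaw-clipped, T&G applied)."""
    geom = beam.machine
    tw = model.leaf_tip_width * 10.0  # mm
    if tw > 0 and grid.resolution > tw / 2.0:
        raise ValueError(
            f"grid resolution {grid.resolution} mm undersamples the "
            f"{tw:.2f} mm leaf-tip band (needs <= tip/2)"
        )
    eff = effective_leaf_positions(cp, model, geom)
    T = model.mlc_transmission
    x = grid.x_centers
    y = grid.y_centers
    xa = eff.bank_a_positions[:, None]
    xb = eff.bank_b_positions[:, None]

    if tw > 0:
        left = 1.0 - np.maximum(xa - x[None, :], 0.0) * (1.0 - T) / tw
        right = 1.0 - np.maximum(x[None, :] - xb, 0.0) * (1.0 - T) / tw
        profiles = np.clip(np.minimum(left, right), T, 1.0)
    else:
        # area-weighted pixel coverage: avoids aliasing of sharp tip edges
        # against the pixel lattice (the closed-form exposure integrals then
        # hold to first order in resolution)
        h = grid.resolution
        cover = np.clip(
            (np.minimum(xb, x[None, :] + h / 2) - np.maximum(xa, x[None, :] - h / 2))
            / h,
            0.0,
            1.0,
        )
        profiles = T + (1.0 - T) * cover
    closed = (eff.bank_b_positions - eff.bank_a_positions) <= 1e-9
    profiles[closed, :] = T

    pair_idx = _row_pair_index(geom, y)
    values = np.zeros((len(y), len(x)))
    valid = pair_idx >= 0
    values[valid, :] = profiles[pair_idx[valid], :]

    tg = model.tg_width * 10.0  # mm
    if tg > 0:
        open_mask = (x[None, :] >= xa) & (x[None, :] <= xb) & ~closed[:, None]
        boundaries = geom.leaf_boundaries
        for j in range(geom.leaf_pair_count - 1):
            yj = boundaries[j + 1]
            rows = np.abs(y - yj) <= tg / 2.0
            if not np.any(rows):
                continue
            exposed = open_mask[j] ^ open_mask[j + 1]
            if not np.any(exposed):
                continue
            sub = values[np.ix_(rows, exposed)]
            values[np.ix_(rows, exposed)] = np.minimum(sub, T)

    in_jaw = (
        (x[None, :] >= cp.jaw_x1)
        & (x[None, :] <= cp.jaw_x2)
        & (y[:, None] >= cp.jaw_y1)
        & (y[:, None] <= cp.jaw_y2)
    )
    values[~in_jaw] = 0.0
    return values


def _apply_field_modifiers(
    values: np.ndarray, model: BeamModelParams, grid: FluenceGrid
) -> np.ndarray:
    if model.source_sigma > 0:
        sigma_px = model.source_sigma * 10.0 / grid.resolution
        values = gaussian_filter(values, sigma_px, mode="constant")
    if model.off_axis_err != 0.0:
        x = grid.x_centers
        y = grid.y_centers
        r2 = x[None, :] ** 2 + y[:, None] ** 2
        values = values * (1.0 + model.off_axis_err * r2 / 100.0**2)
    return values


def control_point_fluence(
    beam: Beam, cp: ControlPoint, model: BeamModelParams, grid: FluenceGrid
) -> FluenceGrid:
    """Fluence of a single control point with blur and off-axis modifier."""
    raw = _cp_fluence_raw(beam, cp, model, grid)
    return grid.like(_apply_field_modifiers(raw, model, grid))


def equivalent_square_side(plan: Plan) -> float:
    """MU-weighted mean aperture area's square-root, mm (monotone size proxy)."""
    from ..complexity.metrics import _aperture_area  # local import avoids cycle

    total = 0.0
    for beam in plan.beams:
        w = beam.mu_weights() * beam.total_mu / plan.total_mu
        for cp, wk in zip(beam.control_points, w):
            total += wk * _aperture_area(beam, cp)
    return float(np.sqrt(max(total, 0.0)))


def accumulate_plan_map(
    plan: Plan,
    model: BeamModelParams,
    grid_spec: GridSpec | None = None,
    grid: Optional[FluenceGrid] = None,
) -> FluenceGrid:
    """MU-weighted plan fluence map (normalized by total plan MU).

    The output-factor modifier scales the whole map by
    ``1 + output_factor_err * s(A_eq)`` with ``s(a) = a / 100 mm`` (monotone
    in field size) and ``A_eq`` the MU-weighted equivalent-square side.  The
    per-ROI depth (PDD) modifier is applied at readout, not here.
    """
    if grid is None:
        grid = grid_for_plan(plan, grid_spec)
    acc = np.zeros_like(grid.values)
    total_mu = plan.total_mu
    for beam in plan.beams:
        weights = beam.mu_weights() * beam.total_mu / total_mu
        for cp, w in zip(beam.control_points, weights):
            if w <= 0:
                continue
            acc += w * _cp_fluence_raw(beam, cp, model, grid)
    acc = _apply_field_modifiers(acc, model, grid)
    if model.output_factor_err != 0.0:
        a_eq = equivalent_square_side(plan)
        acc = acc * (1.0 + model.output_factor_err * a_eq / 100.0)
    return grid.like(acc)
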