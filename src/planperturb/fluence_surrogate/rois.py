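"""Beam's-eye-view regions of interest derived from plan geometry.

All beams share one isocenter-plane BEV (gantry rotation and anatomy are
ignored): the CTV is the high-exposure core of the plan's open-fraction
map, the parallel OAR sits mostly under the leaves, and the serial OAR is
a strip abutting the CTV edge.  Because ROIs come from plan geometry only,
they are identical for baseline and perturbed beam models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from ..machine_plan.types import Plan
from .fluence import FluenceGrid, GridSpec, grid_for_plan, _cp_fluence_raw
from .params import BeamModelParams

# nominal readout depths (cm) per site: (ctv, oar_parallel, oar_serial)
SITE_DEPTHS: Dict[str, tuple] = {
    "prostate": (17.0, 15.0, 16.0),
    "lung": (9.0, 7.0, 8.0),
    "head_and_neck": (8.0, 6.0, 7.0),
    "brain": (7.0, 6.0, 6.0),
    "mesothelioma": (12.0, 10.0, 11.0),
    "other": (10.0, 10.0, 10.0),
}


@dataclass
class RoiSet:
    ctv: np.ndarray  # bool mask on the grid
    oar_parallel: np.ndarray
    oar_serial: np.ndarray
    depths: Dict[str, float] = field(
        default_factory=lambda: {"ctv": 10.0, "oar_parallel": 10.0, "oar_serial": 10.0}
    )

    def __post_init__(self) -> None:
        for name in ("ctv", "oar_parallel", "oar_serial"):
            mask = getattr(self, name)
            if not np.any(mask):
                raise ValueError(f"ROI {name!r} is empty")


def open_fraction_map(plan: Plan, grid: FluenceGrid) -> np.ndarray:
    """MU-weighted fraction of delivery during which each pixel is open.

    Uses bare plan geometry (binary apertures, no beam-model parameters).
    """
    binary = BeamModelParams()
    acc = np.zeros_like(grid.values)
    total_mu = plan.total_mu
    for beam in plan.beams:
        weights = beam.mu_weights() * beam.total_mu / total_mu
        for cp, w in zip(beam.control_points, weights):
            if w <= 0:
                continue
            acc += w * _cp_fluence_raw(beam, cp, binary, grid)
    return acc


def rois_from_plan(
    plan: Plan,
    grid: FluenceGrid | None = None,
    grid_spec: GridSpec | None = None,
    blocked_fraction: float = 0.10,
    min_ctv_pixels: int = 40,
) -> RoiSet:
    """Derive CTV / parallel-OAR / serial-OAR masks from the plan's geometry."""
    if grid is None:
        grid = grid_for_plan(plan, grid_spec)
    frac = open_fraction_map(plan, grid)
    exposed = frac > 0
    if not np.any(exposed):
        raise ValueError("plan exposes no pixels; cannot derive ROIs")
    ref = float(np.percentile(frac[exposed], 95.0))

    x = grid.x_centers
    y = grid.y_centers
    in_jaw = np.zeros_like(frac, dtype=bool)
    for beam in plan.beams:
        for cp in beam.control_points:
            in_jaw |= (
                (x[None, :] >= cp.jaw_x1)
                & (x[None, :] <= cp.jaw_x2)
                & (y[:, None] >= cp.jaw_y1)
                & (y[:, None] <= cp.jaw_y2)
            )

    # take the tightest high-exposure core that still has enough pixels;
    # the strict first setting keeps the CTV inside the uniform interior of
    # swept apertures (edge-ramp pixels would bias mean-dose deviations)
    ctv = None
    for core_fraction, erosion in ((0.98, 4), (0.90, 3), (0.75, 2), (0.50, 0)):
        candidate = frac >= core_fraction * ref
        if erosion:
            candidate = binary_erosion(candidate, iterations=erosion)
        if np.count_nonzero(candidate) >= min_ctv_pixels:
            ctv = candidate
            break
    if ctv is None:
        ctv = frac >= 0.5 * ref

    near = binary_dilation(ctv, iterations=8)
    ring = binary_dilation(ctv, iterations=2)
    oar_serial = near & ~ring & in_jaw
    if not np.any(oar_serial):
        oar_serial = binary_dilation(ctv, iterations=2) & ~ctv

    oar_parallel = in_jaw & (frac <= blocked_fraction * ref) & ~near
    if not np.any(oar_parallel):
        oar_parallel = in_jaw & ~near
    if not np.any(oar_parallel):
        oar_parallel = ~ctv

    d_ctv, d_par, d_ser = SITE_DEPTHS.get(plan.site_label, SITE_DEPTHS["other"])
    return RoiSet(
        ctv=ctv,
        oar_parallel=oar_parallel,
        oar_serial=oar_serial,
        depths={"ctv": d_ctv, "oar_parallel": d_par, "oar_serial": d_ser},
    )
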