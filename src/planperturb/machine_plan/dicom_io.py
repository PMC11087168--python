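"""DICOM RT Plan reading and writing.

Leaf positions are stored per the DICOM convention: the MLCX position list
holds all 60 bank-A (left) tip positions followed by all 60 bank-B tips,
in millimetres at the isocenter plane.  Cumulative meterset weights are
normalized to [0, 1] per beam on read.

A small private block (group 0x7777, creator ``PLANPERTURB``) carries
fields that have no standard RT Plan home: per-control-point nominal times,
the delivery technique label, arc span and the anatomical site label.
"""

from __future__ import annotations

import hashlib
from typing import List

import numpy as np

from . import _dicom as dcm
from .errors import (
    MalformedPlanError,
    PlanValidationError,
    UnsupportedMachineError,
    UnsupportedPlanError,
)
from .types import Beam, ControlPoint, MachineGeometry, Plan, validate_plan

# standard tags
SOP_CLASS_UID = (0x0008, 0x0016)
SOP_INSTANCE_UID = (0x0008, 0x0018)
MODALITY = (0x0008, 0x0060)
RT_PLAN_LABEL = (0x300A, 0x0002)
FRACTION_GROUP_SEQ = (0x300A, 0x0070)
N_FRACTIONS = (0x300A, 0x0078)
BEAM_METERSET = (0x300A, 0x0086)
BEAM_SEQ = (0x300A, 0x00B0)
BLD_SEQ = (0x300A, 0x00B6)
BLD_TYPE = (0x300A, 0x00B8)
N_LEAF_JAW_PAIRS = (0x300A, 0x00BC)
LEAF_BOUNDARIES = (0x300A, 0x00BE)
BEAM_NUMBER = (0x300A, 0x00C0)
BEAM_NAME = (0x300A, 0x00C2)
BEAM_TYPE = (0x300A, 0x00C4)
FINAL_CUMULATIVE_WEIGHT = (0x300A, 0x010E)
N_CONTROL_POINTS = (0x300A, 0x0110)
CP_SEQ = (0x300A, 0x0111)
CP_INDEX = (0x300A, 0x0112)
DOSE_RATE_SET = (0x300A, 0x0115)
BLD_POSITION_SEQ = (0x300A, 0x011A)
LEAF_JAW_POSITIONS = (0x300A, 0x011C)
GANTRY_ANGLE = (0x300A, 0x011E)
CUMULATIVE_WEIGHT = (0x300A, 0x0134)
REF_BEAM_SEQ = (0x300C, 0x0004)
REF_BEAM_NUMBER = (0x300C, 0x0006)

# private block 0x7777 / creator "PLANPERTURB"
PRIV_CREATOR = (0x7777, 0x0010)
PRIV_TIMES = (0x7777, 0x1001)
PRIV_TECHNIQUE = (0x7777, 0x1002)
PRIV_ARC_SPAN = (0x7777, 0x1003)
PRIV_SITE = (0x7777, 0x1004)


def _sop_instance_uid(plan_id: str) -> str:
    digest = hashlib.sha1(plan_id.encode()).hexdigest()[:30]
    return "2.25." + str(int(digest, 16))


def _ds_multi(values) -> str:
    return "\\".join(dcm.format_ds(v) for v in values)


def write_rtplan(plan: Plan, path) -> str:
    """Serialize ``plan`` to a DICOM RT Plan file; returns ``path``.

    Raises :class:`PlanValidationError` when the plan violates its type
    invariants (the file would not round-trip).
    """
    violations = validate_plan(plan)
    if violations:
        raise PlanValidationError("; ".join(violations))

    beam_items: List[dcm.Dataset] = []
    ref_beam_items: List[dcm.Dataset] = []
    for bi, beam in enumerate(plan.beams):
        geom = beam.machine
        bld_items = [
            {BLD_TYPE: ("CS", "ASYMX"), N_LEAF_JAW_PAIRS: ("IS", "1")},
            {BLD_TYPE: ("CS", "ASYMY"), N_LEAF_JAW_PAIRS: ("IS", "1")},
            {
                BLD_TYPE: ("CS", "MLCX"),
                N_LEAF_JAW_PAIRS: ("IS", str(geom.leaf_pair_count)),
                LEAF_BOUNDARIES: ("DS", _ds_multi(geom.leaf_boundaries)),
            },
        ]
        cp_items: List[dcm.Dataset] = []
        for ci, cp in enumerate(beam.control_points):
            positions = np.concatenate([cp.bank_a_positions, cp.bank_b_positions])
            cp_items.append(
                {
                    CP_INDEX: ("IS", str(ci)),
                    CUMULATIVE_WEIGHT: ("DS", dcm.format_ds(cp.cumulative_mu_fraction)),
                    GANTRY_ANGLE: ("DS", dcm.format_ds(cp.gantry_angle)),
                    DOSE_RATE_SET: ("DS", dcm.format_ds(cp.dose_rate)),
                    BLD_POSITION_SEQ: (
                        "SQ",
                        [
                            {
                                BLD_TYPE: ("CS", "ASYMX"),
                                LEAF_JAW_POSITIONS: ("DS", _ds_multi([cp.jaw_x1, cp.jaw_x2])),
                            },
                            {
                                BLD_TYPE: ("CS", "ASYMY"),
                                LEAF_JAW_POSITIONS: ("DS", _ds_multi([cp.jaw_y1, cp.jaw_y2])),
                            },
                            {
                                BLD_TYPE: ("CS", "MLCX"),
                                LEAF_JAW_POSITIONS: ("DS", _ds_multi(positions)),
                            },
                        ],
                    ),
                }
            )
        beam_items.append(
            {
                BEAM_NUMBER: ("IS", str(bi + 1)),
                BEAM_NAME: ("LO", beam.name or f"beam{bi + 1}"),
                BEAM_TYPE: ("CS", "STATIC" if beam.technique == "static-IMRT" else "DYNAMIC"),
                BLD_SEQ: ("SQ", bld_items),
                N_CONTROL_POINTS: ("IS", str(beam.n_cp)),
                FINAL_CUMULATIVE_WEIGHT: ("DS", dcm.format_ds(
                    beam.control_points[-1].cumulative_mu_fraction)),
                CP_SEQ: ("SQ", cp_items),
                PRIV_CREATOR: ("LO", "PLANPERTURB"),
                PRIV_TIMES: ("DS", _ds_multi(cp.nominal_time for cp in beam.control_points)),
                PRIV_TECHNIQUE: ("CS", beam.technique),
                PRIV_ARC_SPAN: ("DS", dcm.format_ds(beam.arc_span)),
            }
        )
        ref_beam_items.append(
            {
                REF_BEAM_NUMBER: ("IS", str(bi + 1)),
                BEAM_METERSET: ("DS", dcm.format_ds(beam.total_mu)),
            }
        )

    ds: dcm.Dataset = {
        SOP_CLASS_UID: ("UI", dcm.RTPLAN_SOP_CLASS),
        SOP_INSTANCE_UID: ("UI", _sop_instance_uid(plan.plan_id)),
        MODALITY: ("CS", "RTPLAN"),
        RT_PLAN_LABEL: ("SH", plan.plan_id),
        FRACTION_GROUP_SEQ: (
            "SQ",
            [{N_FRACTIONS: ("IS", "1"), REF_BEAM_SEQ: ("SQ", ref_beam_items)}],
        ),
        BEAM_SEQ: ("SQ", beam_items),
        PRIV_CREATOR: ("LO", "PLANPERTURB"),
        PRIV_SITE: ("CS", plan.site_label),
    }
    dcm.write_file(path, ds, sop_instance=_sop_instance_uid(plan.plan_id))
    return str(path)


def _bld_lookup(items: List[dcm.Dataset], bld_type: str):
    for item in items:
        if item.get(BLD_TYPE, (None, None))[1] == bld_type:
            return item
    return None


def read_rtplan(path) -> Plan:
    """Parse a DICOM RT Plan file into a :class:`Plan`.

    Cumulative meterset weights are normalized by the beam's final
    cumulative weight; leaf positions are kept in mm at isocenter.
    """
    try:
        ds = dcm.read_file(path)
    except dcm.DicomError as exc:
        raise MalformedPlanError(str(exc)) from exc

    if BEAM_SEQ not in ds:
        raise UnsupportedPlanError("file has no BeamSequence")
    plan_id = str(ds.get(RT_PLAN_LABEL, ("SH", "plan"))[1])
    site = str(ds.get(PRIV_SITE, ("CS", "other"))[1])

    metersets = {}
    for fg in ds.get(FRACTION_GROUP_SEQ, ("SQ", []))[1]:
        for rb in fg.get(REF_BEAM_SEQ, ("SQ", []))[1]:
            metersets[int(float(str(rb[REF_BEAM_NUMBER][1])))] = float(
                str(rb[BEAM_METERSET][1])
            )

    beams: List[Beam] = []
    for beam_item in ds[BEAM_SEQ][1]:
        mlc = _bld_lookup(beam_item.get(BLD_SEQ, ("SQ", []))[1], "MLCX")
        if mlc is None:
            raise UnsupportedPlanError("beam has no MLCX leaf-sequence data")
        n_pairs = int(float(str(mlc[N_LEAF_JAW_PAIRS][1])))
        if n_pairs != 60:
            raise UnsupportedMachineError(
                f"expected a 120-leaf machine (60 pairs), got {n_pairs} pairs"
            )
        boundaries = dcm.ds_values(mlc, LEAF_BOUNDARIES)
        widths = tuple(float(b) for b in np.diff(boundaries))
        geom = MachineGeometry(leaf_pair_count=n_pairs, leaf_widths=widths)

        cp_items = beam_item[CP_SEQ][1]
        cmw = [float(str(item[CUMULATIVE_WEIGHT][1])) for item in cp_items]
        if any(b < a - 1e-9 for a, b in zip(cmw, cmw[1:])):
            raise MalformedPlanError("non-monotonic cumulative meterset weight")
        final = float(str(beam_item.get(FINAL_CUMULATIVE_WEIGHT, ("DS", "0"))[1]))
        if final <= 0:
            final = cmw[-1] if cmw and cmw[-1] > 0 else 1.0

        times = (
            dcm.ds_values(beam_item, PRIV_TIMES)
            if PRIV_TIMES in beam_item
            else [0.0] * len(cp_items)
        )
        technique = str(beam_item.get(PRIV_TECHNIQUE, ("CS", ""))[1])
        if technique not in ("static-IMRT", "sliding-window", "VMAT-arc"):
            beam_type = str(beam_item.get(BEAM_TYPE, ("CS", "DYNAMIC"))[1])
            technique = "static-IMRT" if beam_type == "STATIC" else "VMAT-arc"
        arc_span = (
            float(str(beam_item[PRIV_ARC_SPAN][1])) if PRIV_ARC_SPAN in beam_item else 0.0
        )

        control_points: List[ControlPoint] = []
        jaw = {"x": (-200.0, 200.0), "y": (-200.0, 200.0)}
        for idx, item in enumerate(cp_items):
            pos_items = item.get(BLD_POSITION_SEQ, ("SQ", []))[1]
            mlc_pos = _bld_lookup(pos_items, "MLCX")
            if mlc_pos is None:
                raise UnsupportedPlanError(f"control point {idx} lacks MLCX positions")
            leaves = dcm.ds_values(mlc_pos, LEAF_JAW_POSITIONS)
            if len(leaves) != 2 * n_pairs:
                raise UnsupportedMachineError(
                    f"control point {idx}: {len(leaves)} leaf positions, expected {2 * n_pairs}"
                )
            for axis, names in (("x", ("ASYMX", "X")), ("y", ("ASYMY", "Y"))):
                for name in names:
                    jaws = _bld_lookup(pos_items, name)
                    if jaws is not None:
                        vals = dcm.ds_values(jaws, LEAF_JAW_POSITIONS)
                        jaw[axis] = (vals[0], vals[1])
                        break
            dose_rate = (
                float(str(item[DOSE_RATE_SET][1])) if DOSE_RATE_SET in item else 0.0
            )
            gantry = (
                float(str(item[GANTRY_ANGLE][1])) if GANTRY_ANGLE in item else 0.0
            )
            control_points.append(
                ControlPoint(
                    cumulative_mu_fraction=cmw[idx] / final,
                    gantry_angle=gantry,
                    bank_a_positions=np.array(leaves[:n_pairs]),
                    bank_b_positions=np.array(leaves[n_pairs:]),
                    jaw_x1=jaw["x"][0],
                    jaw_x2=jaw["x"][1],
                    jaw_y1=jaw["y"][0],
                    jaw_y2=jaw["y"][1],
                    nominal_time=times[idx] if idx < len(times) else 0.0,
                    dose_rate=dose_rate,
                )
            )

        beam_number = int(float(str(beam_item.get(BEAM_NUMBER, ("IS", "1"))[1])))
        beams.append(
            Beam(
                control_points=control_points,
                total_mu=metersets.get(beam_number, 100.0),
                technique=technique,  # type: ignore[arg-type]
                machine=geom,
                arc_span=arc_span,
                name=str(beam_item.get(BEAM_NAME, ("LO", ""))[1]),
            )
        )

    return Plan(plan_id=plan_id, site_label=site, beams=beams)
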