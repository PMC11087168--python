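"""JSON dialect for Plan fixtures.

Schema (version 1)::

    {
      "format": "planperturb-plan", "version": 1,
      "plan_id": str, "site_label": str,
      "beams": [
        {
          "technique": str, "total_mu": float, "arc_span": float, "name": str,
          "machine": {"leaf_widths": [...], "max_leaf_position": float,
                      "min_dynamic_gap": float},
          "control_points": [
            {"cumulative_mu_fraction": f, "gantry_angle": f,
             "bank_a_positions": [...60...], "bank_b_positions": [...60...],
             "jaws": [x1, x2, y1, y2], "nominal_time": f, "dose_rate": f}
          ]
        }
      ]
    }
"""

from __future__ import annotations

import json

import numpy as np

from .types import Beam, ControlPoint, MachineGeometry, Plan


def plan_to_dict(plan: Plan) -> dict:
    return {
        "format": "planperturb-plan",
        "version": 1,
        "plan_id": plan.plan_id,
        "site_label": plan.site_label,
        "beams": [
            {
                "technique": beam.technique,
                "total_mu": beam.total_mu,
                "arc_span": beam.arc_span,
                "name": beam.name,
                "machine": {
                    "leaf_widths": list(beam.machine.leaf_widths),
                    "max_leaf_position": beam.machine.max_leaf_position,
                    "min_dynamic_gap": beam.machine.min_dynamic_gap,
                },
                "control_points": [
                    {
                        "cumulative_mu_fraction": cp.cumulative_mu_fraction,
                        "gantry_angle": cp.gantry_angle,
                        "bank_a_positions": cp.bank_a_positions.tolist(),
                        "bank_b_positions": cp.bank_b_positions.tolist(),
                        "jaws": [cp.jaw_x1, cp.jaw_x2, cp.jaw_y1, cp.jaw_y2],
                        "nominal_time": cp.nominal_time,
                        "dose_rate": cp.dose_rate,
                    }
                    for cp in beam.control_points
                ],
            }
            for beam in plan.beams
        ],
    }


def plan_from_dict(data: dict) -> Plan:
    if data.get("format") != "planperturb-plan":
        raise ValueError("not a planperturb plan JSON document")
    beams = []
    for bd in data["beams"]:
        geom = MachineGeometry(
            leaf_pair_count=len(bd["machine"]["leaf_widths"]),
            leaf_widths=tuple(bd["machine"]["leaf_widths"]),
            max_leaf_position=bd["machine"]["max_leaf_position"],
            min_dynamic_gap=bd["machine"]["min_dynamic_gap"],
        )
        cps = [
            ControlPoint(
                cumulative_mu_fraction=cd["cumulative_mu_fraction"],
                gantry_angle=cd["gantry_angle"],
                bank_a_positions=np.array(cd["bank_a_positions"]),
                bank_b_positions=np.array(cd["bank_b_positions"]),
                jaw_x1=cd["jaws"][0],
                jaw_x2=cd["jaws"][1],
                jaw_y1=cd["jaws"][2],
                jaw_y2=cd["jaws"][3],
                nominal_time=cd["nominal_time"],
                dose_rate=cd["dose_rate"],
            )
            for cd in bd["control_points"]
        ]
        beams.append(
            Beam(
                control_points=cps,
                total_mu=bd["total_mu"],
                technique=bd["technique"],
                machine=geom,
                arc_span=bd["arc_span"],
                name=bd.get("name", ""),
            )
        )
    return Plan(plan_id=data["plan_id"], site_label=data["site_label"], beams=beams)


def write_plan_json(plan: Plan, path) -> str:
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan), fh)
    return str(path)


def read_plan_json(path) -> Plan:
    with open(path) as fh:
        return plan_from_dict(json.load(fh))
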