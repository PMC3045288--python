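"""JSON (de)serialization of probability tables, policies and scenarios.

Table schema::

    {
      "risk_table": {factor: {"high": [l, u], "medium": [l, u], "low": [l, u]}},
      "priority_table": {call_kind: {risk_group: [7 floats]}},
      "thresholds": [7 floats],
      "target_distribution": [7 floats]
    }

Floor-plan schema::

    {"spaces": [{"id", "kind", "has_fixed_button", "department"}],
     "edges": [[a, b, meters]]}

Policy schema::

    {"timeouts": {kind: seconds}, "baseline_relaunch": 180,
     "baseline_interrupt_probability": 0.5}
"""

from __future__ import annotations

import json
from pathlib import Path

from . import defaults
from .dispatch import PolicyConfig
from .errors import ConfigError
from .floorplan import FloorPlan
from .model import CallKind, Patient, RiskFactor
from .priority import PriorityTable, RiskTable, ThresholdConfig


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def dump_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


# -- tables -----------------------------------------------------------


def tables_from_json(data: dict):
    """Parse tables; missing sections fall back to the package defaults."""
    if "risk_table" in data:
        rows = {}
        for factor, groups in data["risk_table"].items():
            try:
                rows[RiskFactor(factor)] = (
                    tuple(groups["high"]),
                    tuple(groups["medium"]),
                    tuple(groups["low"]),
                )
            except KeyError as exc:
                raise ConfigError(f"risk_table[{factor}] missing group {exc}") from None
        risk = RiskTable(rows)
    else:
        risk = RiskTable(defaults.DEFAULT_RISK_ROWS)
    if "priority_table" in data:
        prows = {}
        for kind, groups in data["priority_table"].items():
            for group, vec in groups.items():
                prows[(CallKind(kind), group)] = tuple(vec)
        prio = PriorityTable(prows)
    else:
        prio = PriorityTable(defaults.DEFAULT_PRIORITY_ROWS)
    thresholds = ThresholdConfig(
        data.get("thresholds", defaults.DEFAULT_THRESHOLDS)
    )
    target = tuple(
        data.get("target_distribution", defaults.DEFAULT_TARGET_DISTRIBUTION)
    )
    return risk, prio, thresholds, target


def tables_to_json(risk: RiskTable, prio: PriorityTable, thresholds, target) -> dict:
    return {
        "risk_table": {
            factor.value: {
                "high": list(triple[0]),
                "medium": list(triple[1]),
                "low": list(triple[2]),
            }
            for factor, triple in risk.rows.items()
        },
        "priority_table": _nest_priority(prio),
        "thresholds": list(thresholds),
        "target_distribution": list(target),
    }


def _nest_priority(prio: PriorityTable) -> dict:
    nested: dict = {}
    for (kind, group), vec in prio.rows.items():
        nested.setdefault(kind.value, {})[group] = [float(x) for x in vec]
    return nested


# -- floor plan / policy ------------------------------------------------


def floorplan_from_json(data: dict) -> FloorPlan:
    return FloorPlan.from_json(data)


def policy_from_json(data: dict) -> PolicyConfig:
    kwargs = {}
    if "timeouts" in data:
        kwargs["timeouts"] = {CallKind(k): int(v) for k, v in data["timeouts"].items()}
    if "baseline_relaunch" in data:
        kwargs["baseline_relaunch"] = int(data["baseline_relaunch"])
    if "baseline_interrupt_probability" in data:
        kwargs["baseline_interrupt_probability"] = float(
            data["baseline_interrupt_probability"]
        )
    return PolicyConfig(**kwargs)


def policy_to_json(policy: PolicyConfig) -> dict:
    return {
        "timeouts": {k.value: v for k, v in policy.timeouts.items()},
        "baseline_relaunch": policy.baseline_relaunch,
        "baseline_interrupt_probability": policy.baseline_interrupt_probability,
    }


# -- scenario snapshots -------------------------------------------------


def scenario_to_json(scenario) -> dict:
    """Serialize a concrete scenario instance (census + plan + tables)."""
    from . import defaults

    return {
        "department": scenario.config.department,
        "patients": {
            p.id: {
                "room": p.room,
                "bed": p.bed,
                "risk_factors": sorted(f.value for f in p.risk_factors),
                "preferred_characteristics": sorted(p.preferred_characteristics),
            }
            for p in scenario.patients
        },
        "floor_plan": scenario.plan.to_json(),
        "tables": tables_to_json(
            scenario.risk_table,
            scenario.priority_table,
            scenario.thresholds,
            defaults.DEFAULT_TARGET_DISTRIBUTION,
        ),
    }


def scenario_from_json(data: dict):
    """Reconstruct a Scenario from a snapshot written by ``scenario_to_json``."""
    from .scenario import Scenario, ScenarioConfig

    plan = floorplan_from_json(data["floor_plan"])
    risk, prio, thresholds, _ = tables_from_json(data.get("tables", {}))
    cfg = ScenarioConfig(department=data.get("department", "dept"))
    patients = []
    for pid, entry in sorted(data["patients"].items()):
        patients.append(
            Patient(
                id=pid,
                bed=entry.get("bed", ""),
                room=entry["room"],
                department=cfg.department,
                risk_factors={RiskFactor(f) for f in entry.get("risk_factors", [])},
                preferred_characteristics=set(
                    entry.get("preferred_characteristics", [])
                ),
                current_location=entry["room"],
            )
        )
    return Scenario(
        config=cfg,
        plan=plan,
        risk_table=risk,
        priority_table=prio,
        thresholds=thresholds,
        patients=patients,
    )
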