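"""Inspect the default ward layout and dispatch a single call by hand.

Builds the default floor plan (13 two-bed rooms along a corridor spine,
per-room sanitary spaces, nursing post, three remote areas), generates a
census and a night roster, and traces one dispatch decision.
"""

import numpy as np

from wardcall import (
    CallKind,
    PolicyConfig,
    Role,
    ScenarioConfig,
    assign_responsibilities,
    build_scenario,
    generate_staff,
    launch_call,
    oncs_select,
)
from wardcall.model import KnowledgeBase

scenario = build_scenario(seed=7)
plan = scenario.plan
print(f"spaces: {len(plan.spaces)}, patients: {len(scenario.patients)}")
print(f"walk nursing post -> smoking area: {plan.distance('nursing_post', 'smoking_area'):.0f} m")

kb = KnowledgeBase()
for p in scenario.patients:
    kb.add_patient(p)
staff = generate_staff(scenario.config, ("week", "night"), np.random.default_rng(7))
for s in staff:
    kb.add_staff(s)
nurses = [s for s in staff if s.role is Role.NURSE]
blocks = assign_responsibilities(scenario.patients, nurses)
for nurse_id, block in blocks.items():
    print(f"nurse {nurse_id} responsible for {len(block)} patients")

patient = scenario.patients[0]
call = launch_call(kb, patient.id, CallKind.NORMAL, plan.space(patient.room))
decision = oncs_select(call, kb, plan, PolicyConfig())
print(
    f"call from {patient.id} in {patient.room} -> nurse {decision.assignee} "
    f"(stage: {decision.stage.value})"
)
# With everyone free, the cascade stops at its first stage: the nurse
# responsible for the calling patient's room block.
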