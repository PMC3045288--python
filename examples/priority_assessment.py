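"""Assess the priority of one nurse call from a patient's risk factors.

A patient with diabetes and a heart disease presses the call button in
their room. Each risk factor bounds the chance that the patient belongs to
the High/Medium/Low risk group; intersecting the per-factor intervals
combines the evidence, propagating through the call-kind table yields a
probability interval per priority level, and the threshold walk picks the
single level used for dispatch.
"""

from wardcall import (
    CallKind,
    RiskFactor,
    assign_priority,
    assign_risk_groups,
    priority_bounds,
)
from wardcall.defaults import (
    default_priority_table,
    default_risk_table,
    default_thresholds,
)

factors = {RiskFactor.DIABETES, RiskFactor.HEART_DISEASE}
assignment = assign_risk_groups(factors, default_risk_table())
print("combined risk-group intervals:")
for group, iv in assignment.as_dict().items():
    print(f"  {group:<7} [{iv.lower:g}, {iv.upper:g}]")

bounds = priority_bounds(assignment, CallKind.NORMAL, default_priority_table())
names = ("Highest", "High", "AboveNormal", "Normal", "BelowNormal", "Low", "Lowest")
print("\npriority probability intervals (normal call):")
for name, iv in zip(names, bounds):
    print(f"  {name:<12} [{iv.lower:g}, {iv.upper:g}]")

level = assign_priority(bounds, default_thresholds())
print(f"\nassigned priority: {level.name}")
# The lower bounds (0, 0.1, 0.3, 0.1, 0, 0, 0) walked against the
# department thresholds (0.21, 0.3, 0.24, 0, 0.05, 0, 0) stop at
# AboveNormal: this patient's call outranks a risk-free patient's call.
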