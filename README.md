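# wardcall

Person-oriented nurse-call dispatch with probabilistic priority
assessment, plus a discrete-event ward simulator that compares it against
the classic place-oriented broadcast system.

## The problem

Traditional nurse-call systems are *place-oriented*: call buttons are
fixed to room walls, every nurse of the department is paged at once, and
whoever reaches the room first handles the call. Nobody knows the call's
urgency, patients cannot call from a hallway or the smoking area, and
several nurses may interrupt their work for the same call.

`wardcall` implements the *person-oriented* alternative for hospital
operations researchers and nurse-call system designers: each patient
carries a mobile button, the system knows the patient's risk profile and
every staff member's location, task and characteristics, and exactly one
staff member is dispatched per call.

Two components carry the method:

**1. Probabilistic priority assessment.** Clinical knowledge about a risk
factor *f* is a probability interval: bounds on the chance that a patient
with *f* is a High/Medium/Low-risk patient (e.g. a diabetic patient has at
least 50% chance of being high risk, encoded `[0.5, 1]`). For a patient
with factors F, the group membership interval is the intersection

> P(group r) ∈ [ max_f l_{f,r} , min_f u_{f,r} ]

A conditional table c gives P(priority k | call kind, group r); linear
interval propagation yields per-priority bounds with lower ends
`L_k = Σ_r c_{r,k} · l_r`. The assigned priority is found by a threshold
walk: scan the seven levels from Highest to Lowest and return the first
level k with `L_k ≥ θ_k` (some θ is 0, so the walk terminates). The
threshold vector θ is calibrated by an exact grid search minimizing the L1
distance between the achieved priority shares of a synthetic call
population and a target distribution.

**2. Staged dispatch.** For patient and assistance calls, candidates are
searched in a fixed cascade — responsible nurse (also if busy with a
strictly lower-priority task) → free department handlers (+ busy-with-lower
ones for Highest/High calls) → the whole hospital → closest free, willing,
qualified → closest unconditionally — with preference-aware ranking,
maker exclusion, and a time-out that reruns the search when an assignee
does not respond. Urgency calls go to the *nearest* staff member, busy or
not; technical calls always get the Lowest priority.

The simulator runs a synthetic 26-bed ward (84.62% occupancy → 22
patients) through 8-hour shifts under both policies with common random
numbers, and reports nurse arrival-time distributions, per-nurse workload
shares, unnecessary arrivals, and calls that are impossible to place under
the broadcast system.

## Worked example

```python
from wardcall import (CallKind, RiskFactor, assign_priority,
                      assign_risk_groups, priority_bounds)
from wardcall.defaults import (default_priority_table, default_risk_table,
                               default_thresholds)

factors = {RiskFactor.DIABETES, RiskFactor.HEART_DISEASE}
assignment = assign_risk_groups(factors, default_risk_table())
bounds = priority_bounds(assignment, CallKind.NORMAL, default_priority_table())
level = assign_priority(bounds, default_thresholds())
```

Running `python examples/priority_assessment.py` prints:

```
combined risk-group intervals:
  high    [0.5, 1]
  medium  [0, 0.3]
  low     [0, 0.1]

priority probability intervals (normal call):
  Highest      [0, 0]
  High         [0.1, 0.2]
  AboveNormal  [0.3, 0.69]
  Normal       [0.1, 0.44]
  BelowNormal  [0, 0.06]
  Low          [0, 0.01]
  Lowest       [0, 0]

assigned priority: ABOVE_NORMAL
```

The patient is at least 50% likely to be high risk, at most 30% medium and
at most 10% low. Propagated through the normal-call table, the Above
Normal level is the first whose lower bound (0.30) clears its threshold
(0.24), so this call outranks the plain Normal priority a risk-free
patient's call would get.

`python examples/compare_policies.py` simulates ten paired night shifts
(2 nurses, 22 patients) and prints, for this build:

```
person-oriented:  median arrival  25 s, unnecessary arrivals 0,  impossible 0
place-oriented:   median arrival 190 s, unnecessary arrivals 46, impossible 107
```

Single-assignee dispatch never sends a second nurse to a handled call and
answers calls made away from fixed buttons; the broadcast baseline loses
those calls and stalls whenever every paged nurse ignores a broadcast
until its 180-second relaunch.

## Command line

```bash
wardcall priority --risk-factors diabetes,heart_disease --call-kind normal
wardcall calibrate --n 22500 --seed 42
wardcall generate --seed 3 --out scenario.json
wardcall simulate --policy place --shift night_week --runs 5 --seed 3 --out out/
wardcall compare --runs 5 --seed 42 --out out/
wardcall report --logs out/ --out report/
```

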