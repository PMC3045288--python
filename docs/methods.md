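# Methods

This note documents the models implemented in `wardcall`, their
assumptions, the provenance of every default parameter, and the design
choices made where the underlying method description left the design
open.

## Probabilistic priority assessment

### Model

Uncertainty about a patient's risk-group membership is represented by
closed probability intervals rather than point probabilities, because the
underlying clinical judgments are of the form "at least 50% chance". Three
propositions are tracked per patient — membership in the High, Medium and
Low risk group — each with its own interval. They are deliberately **not**
constrained to sum to one across groups: the three memberships are treated
as separate uncertain propositions. A sum constraint would be incompatible
with the reference worked example, whose High-priority lower bound
0.1 = 0.2 × 0.5 requires the group intervals to enter the propagation
independently.

For a patient with risk factors F, each group's interval is the
intersection of the per-factor intervals: `[max lower, min upper]`. An
empty intersection means the configured table is self-contradictory for
that factor combination and raises an error naming the factors. A patient
with **no** risk factors is treated as certainly low-risk
(high = medium = [0,0], low = [1,1]) rather than vacuously unknown
([0,1] everywhere); the degenerate intervals make the propagated priority
distribution collapse to the low-risk row of the conditional table, which
is the intended behavior for an unremarkable patient.

Propagation to priorities is linear interval arithmetic: with conditional
probabilities c(k | kind, r) and group intervals [l_r, u_r],

    L_k = Σ_r c_{r,k} · l_r        U_k = min(1, Σ_r c_{r,k} · u_r)

Blank table cells contribute zero. Note that these upper bounds are the
loose linear ones; a probabilistic-description-logic entailment engine can
produce tighter (or structurally different) upper bounds for the same
inputs. This implementation makes no attempt to reproduce any particular
entailment semantics for the uppers, because the decision rule below
consumes **only the lower bounds**, and all reference lower bounds are
reproduced exactly by the linear form.

### Threshold decision rule

The single assigned priority is the first level k, scanning Highest →
Lowest, with `L_k ≥ θ_k`. The threshold vector must contain a zero so the
walk always returns. The default thresholds are
(0.21, 0.30, 0.24, 0, 0.05, 0, 0).

A consequence worth stating explicitly: with θ(Normal) = 0, no call can
ever be assigned Below Normal, Low or Lowest — the walk stops at Normal at
the latest, since every lower bound is ≥ 0. In particular a risk-free
patient's normal call (lower bounds 0, 0, 0, 0.6, 0.3, 0.1, 0) is assigned
**Normal** under these defaults. Looser descriptions of this configuration
sometimes suggest such calls sit at Below Normal; that outcome is
arithmetically impossible under this rule with these thresholds, and the
test suite pins the Normal outcome deliberately.

### Threshold calibration

`calibrate_thresholds` finds the grid vector (step 0.01 by default, the
resolution implied by thresholds like 0.21 and 0.24) minimizing the L1
distance between the achieved priority shares of a sample of call
bound-vectors and a target distribution (default 5/10/25/35/25/0/0
percent), with ties broken by the lexicographically smallest vector.

Enumerating the full grid (101^7 points) is infeasible, but it is also
unnecessary: for level k, the set of sample vectors captured by a
threshold θ_k is a step function of θ_k that only changes at distinct
sample values of that coordinate. Per level, only the smallest grid value
realizing each distinct capture set needs to be considered — any other
grid value assigns identical priorities with a lexicographically larger
vector. A depth-first enumeration over these reduced candidate sets, with
branch-and-bound pruning on the accumulated L1 and an all-zero-suffix
collapse once every sample is captured, yields the exact optimum; on the
default 22,500-call sample it runs in well under a second because the
generated lower-bound vectors take only a few dozen distinct values. The
unit tests verify exactness against full grid enumeration on coarse
grids.

The residual L1 at the optimum (~0.12 on the default sample) is not a
search failure: achieved shares move in discrete jumps as a threshold
crosses a bound value, so the target is generally not exactly attainable.

## Ward model

### Floor plan

Geometry is abstracted to a connected weighted graph; edge weights are
walking distances in meters. The default plan is synthetic: 13 two-bed
rooms (26 beds) on a corridor spine, a sanitary space per room, a nursing
post, a head-nurse office, and three remote spaces (smoking area,
cafeteria, CT scanner) at 120/180/150 m from the ward exit — i.e.
120/180/150 s one way at the 1 m/s walking speed. The remote distances and
the within-ward edge lengths are plausible values, not measurements, and
are fully overridable through the floor-plan JSON. Fixed call buttons
exist only in patient rooms and sanitary spaces; this is what makes
corridor and remote calls impossible under the place-oriented policy.

### Scenario generation

The census is `round(26 × 0.8462) = 22` patients. Per patient, the number
of risk factors is drawn from the proportions 10:10:8:2 for 0/1/2/>2
factors (">2" realized as exactly 3; no upper bound is given by the
source material, and 3 keeps the tail conservative). Factors are drawn
without replacement proportional to reference weights; after each draw,
the weights of the drawn factor's known co-occurrence partners (e.g. COPD
and tracheotomy) are multiplied by a boost of ×3 — the pair list is given,
the strength is not, and ×3 makes the listed pairs clearly over-represented
without dominating the census. Zero-weight factors stay in the enumeration
but are never sampled.

The risk table ships two reference rows (diabetes `[0.5,1]/[0,0.3]/[0,0.2]`,
heart disease `[0.5,1]/[0,0.4]/[0,0.1]`); the remaining 13 rows are
**synthetic**, following the same `[l,1] / [0,u] / [0,u]` shape, which
guarantees every factor combination has a consistent intersection. The
priority table ships the reference normal-call rows; the rows for
sanitary, service, assistance and sanitary-assistance calls are synthetic,
shaped so that assistance-type calls concentrate on Highest/High, sanitary
calls sit a notch above normal calls and service calls stay in the middle
band under the default thresholds. All synthetic tables are
config-overridable JSON.

Staffing: 5/4/2 nurses for week early/late/night, 4/3/2 at weekends
("1 or 2" night nurses resolved to 2 by default), plus a head nurse who is
registered but never a dispatch candidate. All staff speak Dutch; English/
French/German are sampled at 80/70/20%. 2% of patients speak only French
and 3% only German; they prefer a matching-language helper. Other
preference attributes default to none. Responsibilities split the rooms
along the corridor into contiguous blocks differing by at most one
patient, one block per nurse.

## Simulator

A synchronous tick engine; one tick is 5 seconds. Walking speed is one
step of 5 m per tick (1 m/s); the step length is configurable for other
readings of "advance a fixed distance per time step". Eight-hour shifts
are 5,760 ticks.

**Patients** move between their room, its sanitary space, the corridor and
the remote areas according to a time-share budget (default 80% own room,
8% sanitary, 12% elsewhere — the ward's patients are mobile but spend most
of their time in their rooms) with exponential dwell times. Calls arrive
per patient as a per-tick Bernoulli(λ) with λ = 0.001164021, the
per-tick approximation of the stated Poisson rate (λ·tick ≪ 1); at 5-s
ticks this yields ≈147 calls per 8-hour shift for 22 patients. A calling
patient stands still until treated. Call launch times, reasons and service
durations are pre-generated from a policy-independent random substream, so
the two policies of a paired comparison face the identical call schedule
(common random numbers); a scheduled launch is suppressed only if that
patient is still waiting on an open call. The reason mix (toileting, pain
medication, IV alarm, repositioning, beverage, accidental) and the
lognormal service durations (means 30–300 s) are synthetic defaults.

**Nurses**, when idle, draw background tasks from a synthetic mix
(medication round / hygiene care / administration / transfers / break)
whose priorities imply their interruptibility (Low/Lowest always
interruptible, High never, the middle band sometimes). While treating a
call a nurse escalates at most one assistance call for that treatment,
with per-tick probability 0.0007386 (the stated rate lacks a time basis;
per tick over a multi-minute treatment yields a few assistance calls per
shift, enough to exercise the assistance path). An assistance call made
inside a sanitary space becomes a sanitary-assistance call.

**Person-oriented policy.** Calls are prioritized by the engine above and
dispatched through the staged cascade. A free assignee accepts; a busy one
interrupts a task iff the call's priority is ≥ the task's, and interrupts
a call being handled only for a strictly higher priority. Interrupted
non-call tasks are queued with their remaining duration and resumed later;
an interrupted call reverts to active and is re-dispatched immediately. An
assignee who ignores keeps the call pending (taking it when freed) and the
dispatch re-runs at the 180-s time-out, excluding only the immediately
preceding assignee; exclusions reset when exhausted so a single-nurse ward
stays live.

**Place-oriented baseline.** Calls from button-equipped spaces are
broadcast to every nurse of the department; calls from anywhere else are
flagged impossible and never dispatched (the patient gives up waiting
after 300 s and resumes moving; the call stays on the books as impossible
and unanswered). A free nurse always responds — ignoring a broadcast is
modeled as a decision about abandoning one's current work, which a free
nurse does not face; a busy nurse responds with probability 0.5 (the
"chooses randomly" rule; no rate is specified). Nurses already committed
to a call reconsider only when a waiting call is re-broadcast at its
180-second relaunch cadence, again by coin flip. An interrupted treatment
retains its progress and resumes from the remaining duration when a nurse
returns — without this the 2-nurse night shift is dynamically unstable
(treatments restart endlessly and almost nothing completes). Responders
race; the first to arrive treats the call, and the call disappears from
beepers when treatment starts, with one tick of information latency, so a
second nurse arriving near-simultaneously still produces an *unnecessary
arrival* while later responders turn back.

### Metrics

Arrival time per answered call is first-treatment-start minus launch,
histogrammed in 5-s bins up to 60 s and 60-s bins beyond (the two-regime
axis used for arrival-time reporting). Per-run workload is each nurse's
share of *completed* calls, summarized as max, min, number of idle nurses
and the population standard deviation of the per-nurse percentages.
Unnecessary arrivals are recomputed from the raw event log (an `arrived`
event at a call another nurse is already treating), independent of the
engine's own bookkeeping. Impossible and end-of-shift unanswered calls are
tallied separately; arrival-time statistics never include never-answered
calls.

## What the synthetic scenarios do and do not show

The generator reproduces the reference department's documented structure:
census size, risk-factor mix and weights, staffing levels, responsibility
structure, language profiles, the call rate, and the 180-s baseline
cadence. It does **not** reproduce the unavailable task-time and
call-reason distributions, the measured walk times, or any behavioral
heterogeneity between nurses — all nurses here are statistically
identical. Consequently the simulator supports *directional* conclusions
(single-assignee dispatch eliminates unnecessary arrivals; broadcast
systems lose out-of-room calls; relaunch peaks at 180-s multiples;
person-oriented dispatch answers faster in the median and spreads workload
more evenly at night staffing), not the reproduction of any particular
reference curve. Between the two top priority classes the dispatch rules
are deliberately identical (both may take busy-with-lower staff), so their
arrival-time means are statistically indistinguishable in this model; the
ordering tests treat that comparison one-sidedly with sampling error
rather than asserting a strict gap.

## Numerical choices

- Probability comparisons in the threshold walk and the calibration use a
  1e-12 tolerance; interval intersection tolerates 1e-12 of float fuzz
  before declaring inconsistency.
- Ties: candidate ranking orders by (refusal, matched preferences,
  distance, staff id); nearest-staff queries break distance ties by
  smallest id; call choice breaks priority and distance ties by sequence
  number; calibration breaks L1 ties lexicographically.
- Degenerate inputs: empty candidate sets, empty calibration samples,
  unknown spaces/entities, and illegal status transitions raise typed
  errors (`wardcall.errors`); simulation config validation happens before
  the first tick.
- All simulator randomness derives from one integer seed through named
  `numpy` `SeedSequence` substreams (schedule, roster, movement, tasks,
  policy decisions), so runs are exactly reproducible and paired policies
  share the call stream.

## Problem sizes used by the test suite

The packaged tests run paired 8-hour shifts at the reference staffing
(30-seed blocks for the night-shift comparison; the full 30 × 6-shift
design for the priority-ordering check) and the full 22,500-call
calibration; property tests use small randomized fixtures with exhaustive
oracles (graphs ≤ 8 nodes, grids coarse enough to enumerate fully).
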