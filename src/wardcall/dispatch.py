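"""Staff-selection policies.

Two policies are implemented. The person-oriented policy walks a fixed
cascade of candidate stages (responsible nurse, department, whole hospital,
closest qualified, closest unconditionally) and always yields exactly one
assignee. The place-oriented baseline broadcasts to every nurse of the
department — but only when the call originates in a space with a fixed
call button, otherwise the call is impossible to handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import ConfigError, NoCandidateError, WardCallError
from .floorplan import FloorPlan, nearest
from .model import (
    Call,
    CallKind,
    KnowledgeBase,
    PriorityLevel,
    Role,
    StaffMember,
    TaskKind,
    allowed_handlers,
)


class DispatchStage(str, Enum):
    RESPONSIBLE = "responsible"
    DEPARTMENT_FREE = "department_free"
    DEPARTMENT_BUSY_LOWER = "department_busy_lower"
    HOSPITAL_FREE = "hospital_free"
    HOSPITAL_BUSY_LOWER = "hospital_busy_lower"
    CLOSEST_QUALIFIED = "closest_qualified"
    CLOSEST_ANY = "closest_any"
    BROADCAST = "broadcast"
    IMPOSSIBLE = "impossible"


@dataclass(frozen=True)
class DispatchDecision:
    call_id: int
    stage: DispatchStage
    clock: int = 0
    assignee: Optional[str] = None
    broadcast_set: Optional[frozenset] = None

    def __post_init__(self):
        has_assignee = self.assignee is not None
        has_broadcast = self.broadcast_set is not None
        if self.stage is DispatchStage.IMPOSSIBLE:
            if has_assignee or has_broadcast:
                raise WardCallError("impossible dispatch carries no recipients")
        elif has_assignee == has_broadcast:
            raise WardCallError(
                "exactly one of assignee / broadcast_set must be populated"
            )


@dataclass
class PolicyConfig:
    """Timeouts and baseline behavior knobs.

    Urgency calls never time out (someone near is always dispatched
    immediately), so ``timeouts`` must not contain an urgency entry.
    """

    timeouts: dict = field(
        default_factory=lambda: {
            CallKind.NORMAL: 180,
            CallKind.SANITARY: 180,
            CallKind.SERVICE: 180,
            CallKind.ASSISTANCE: 180,
            CallKind.SANITARY_ASSISTANCE: 180,
            CallKind.MEDICAL: 180,
            CallKind.TECHNICAL: 180,
        }
    )
    baseline_relaunch: int = 180
    baseline_interrupt_probability: float = 0.5

    def __post_init__(self):
        self.timeouts = {CallKind(k): int(v) for k, v in self.timeouts.items()}
        if CallKind.URGENCY in self.timeouts:
            raise ConfigError("urgency calls have no time-out")
        if not (0.0 <= self.baseline_interrupt_probability <= 1.0):
            raise ConfigError("baseline_interrupt_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# Candidate predicates and ranking
# ---------------------------------------------------------------------------


def _busy_with_lower(member: StaffMember, call_priority: Optional[PriorityLevel]) -> bool:
    """Busy but the current task has strictly lower priority than the call."""
    return (
        member.current_task is not None
        and call_priority is not None
        and member.current_task.priority < call_priority
    )


def _callable_now(member: StaffMember, call: Call) -> bool:
    return member.free or _busy_with_lower(member, call.priority)


def rank_candidates(
    candidates: Sequence[StaffMember], patient, plan: FloorPlan
) -> list[StaffMember]:
    """Order candidates for a patient's call.

    Staff who refuse the patient are demoted to the end but never removed
    (refusals steer choice among available helpers, they never veto).
    Within each group the order is: most satisfied preferred
    characteristics first, then nearest, then smallest id.
    """
    prefs = set(getattr(patient, "preferred_characteristics", set()) or set())
    target = getattr(patient, "current_location", None)
    pid = getattr(patient, "id", patient)

    def key(member: StaffMember):
        refused = 1 if pid in member.refuses_patients else 0
        matched = len(prefs & member.characteristics)
        dist = (
            plan.distance(member.current_location, target)
            if target is not None
            else 0.0
        )
        return (refused, -matched, dist, member.id)

    return sorted(candidates, key=key)


def _exclusions(call: Call) -> set:
    return set(call.excluded) | {call.maker}


# ---------------------------------------------------------------------------
# Person-oriented selection
# ---------------------------------------------------------------------------

PERSON_POLICY_KINDS = frozenset(
    {
        CallKind.NORMAL,
        CallKind.SANITARY,
        CallKind.SERVICE,
        CallKind.ASSISTANCE,
        CallKind.SANITARY_ASSISTANCE,
    }
)


def oncs_select(
    call: Call, kb: KnowledgeBase, plan: FloorPlan, policy: PolicyConfig
) -> DispatchDecision:
    """Person-oriented staff selection for patient and assistance calls.

    Stages, in order:

    1. the patient's responsible nurse, if free or busy with a strictly
       lower-priority task;
    2. allowed handlers on the patient's department: free ones, and — only
       for Highest/High calls — ones busy with a lower-priority task;
    3. the same over the whole hospital;
    4. the closest free, willing and qualified staff member;
    5. the closest qualified staff member unconditionally.

    Within a stage candidates are ranked by :func:`rank_candidates`. The
    call's maker and staff excluded by earlier time-outs never qualify.
    The head nurse is never a candidate.
    """
    if call.kind not in PERSON_POLICY_KINDS:
        raise ConfigError(
            f"person-oriented cascade does not apply to {call.kind.value} calls"
        )
    handlers = allowed_handlers(call.kind)
    excluded = _exclusions(call)
    patient = kb.get_patient(call.patient) if call.patient else None
    target = call.origin_space

    def qualified(member: StaffMember) -> bool:
        return (
            member.role in handlers
            and member.role is not Role.HEAD_NURSE
            and member.id not in excluded
        )

    pool = [m for m in kb.staff.values() if qualified(m)]
    if not any(
        m.role in handlers and m.role is not Role.HEAD_NURSE
        for m in kb.staff.values()
    ):
        raise NoCandidateError(f"no staff can handle {call.kind.value} calls")

    def decision(member: StaffMember, stage: DispatchStage) -> DispatchDecision:
        return DispatchDecision(
            call_id=call.sequence_number,
            stage=stage,
            clock=kb.clock,
            assignee=member.id,
        )

    # stage 1: responsible nurse / caretaker
    if patient is not None:
        responsible = kb.responsible_nurse(patient.id)
        if (
            responsible is not None
            and qualified(responsible)
            and _callable_now(responsible, call)
        ):
            return decision(responsible, DispatchStage.RESPONSIBLE)

    high = call.priority in (PriorityLevel.HIGHEST, PriorityLevel.HIGH)
    department = patient.department if patient is not None else None

    def scoped(members, department_only: bool):
        if not department_only:
            return list(members)
        return [m for m in members if department in m.departments]

    for department_only, free_stage, busy_stage in (
        (True, DispatchStage.DEPARTMENT_FREE, DispatchStage.DEPARTMENT_BUSY_LOWER),
        (False, DispatchStage.HOSPITAL_FREE, DispatchStage.HOSPITAL_BUSY_LOWER),
    ):
        if department_only and department is None:
            continue
        in_scope = scoped(pool, department_only)
        free = [m for m in in_scope if m.free]
        if free:
            ranked = rank_candidates(free, patient or call.patient, plan)
            return decision(ranked[0], free_stage)
        if high:
            busy_lower = [m for m in in_scope if _busy_with_lower(m, call.priority)]
            if busy_lower:
                ranked = rank_candidates(busy_lower, patient or call.patient, plan)
                return decision(ranked[0], busy_stage)

    # stage 4: closest free, willing, qualified
    pid = patient.id if patient is not None else None
    willing_free = [
        m for m in pool if m.free and (pid is None or pid not in m.refuses_patients)
    ]
    if willing_free:
        return decision(
            nearest(plan, willing_free, target), DispatchStage.CLOSEST_QUALIFIED
        )

    # stage 5: closest qualified staff member, busy or not
    if not pool:
        raise NoCandidateError(
            f"call {call.sequence_number}: all qualified staff excluded"
        )
    return decision(nearest(plan, pool, target), DispatchStage.CLOSEST_ANY)


def urgency_select(call: Call, kb: KnowledgeBase, plan: FloorPlan) -> DispatchDecision:
    """Urgency calls go to the nearest medical staff member, busy or not."""
    handlers = allowed_handlers(CallKind.URGENCY)
    candidates = [
        m
        for m in kb.staff.values()
        if m.role in handlers
        and m.role is not Role.HEAD_NURSE
        and m.id != call.maker
    ]
    if not candidates:
        raise NoCandidateError("no medical staff available for urgency call")
    member = nearest(plan, candidates, call.origin_space)
    return DispatchDecision(
        call_id=call.sequence_number,
        stage=DispatchStage.CLOSEST_ANY,
        clock=kb.clock,
        assignee=member.id,
    )


def low_priority_select(call: Call, kb: KnowledgeBase) -> DispatchDecision:
    """Medical and technical calls: simple role-based selection.

    Technical calls always get the Lowest priority and go to a member of
    the technical staff. Medical calls prefer a free doctor responsible for
    the patient, then any free doctor, then queue with the responsible
    doctor.
    """
    if call.kind is CallKind.TECHNICAL:
        call.priority = PriorityLevel.LOWEST
        role = Role.TECHNICAL_STAFF
    elif call.kind is CallKind.MEDICAL:
        role = Role.DOCTOR
    else:
        raise ConfigError(
            f"low_priority_select does not apply to {call.kind.value} calls"
        )
    members = sorted(
        (m for m in kb.staff.values() if m.role is role), key=lambda m: m.id
    )
    if not members:
        raise NoCandidateError(f"no {role.value} in the knowledge base")

    responsible = None
    if call.patient is not None:
        for m in members:
            if call.patient in m.responsible_for:
                responsible = m
                break
    ordered = []
    if responsible is not None and responsible.free:
        ordered.append(responsible)
    ordered.extend(m for m in members if m.free and m is not responsible)
    chosen = ordered[0] if ordered else (responsible or members[0])
    return DispatchDecision(
        call_id=call.sequence_number,
        stage=DispatchStage.RESPONSIBLE
        if chosen is responsible
        else DispatchStage.HOSPITAL_FREE,
        clock=kb.clock,
        assignee=chosen.id,
    )


def on_timeout(
    call: Call, kb: KnowledgeBase, plan: FloorPlan, policy: PolicyConfig, clock: int
) -> Optional[DispatchDecision]:
    """Re-run selection after an assignee failed to respond in time.

    The previous assignee joins the call's exclusion set; when exclusions
    exhaust every candidate they are cleared so a single-nurse ward stays
    live. A call already being treated is left alone.
    """
    from .model import CallStatus  # local import to avoid cycle at module load

    if call.status in (CallStatus.BUSY, CallStatus.FINISHED):
        return None
    if call.assignee is not None:
        call.excluded.add(call.assignee)
    call.relaunch_count += 1
    kb.clock = clock
    try:
        decision = oncs_select(call, kb, plan, policy)
    except NoCandidateError:
        call.excluded.clear()
        decision = oncs_select(call, kb, plan, policy)
    call.assignee = decision.assignee
    return decision


def place_oriented_dispatch(
    call: Call, kb: KnowledgeBase, policy: PolicyConfig, plan: FloorPlan
) -> DispatchDecision:
    """Place-oriented baseline: broadcast to every nurse of the department.

    Calls originating in a space without a fixed button cannot be signalled
    at all and are flagged impossible. Unanswered broadcast calls are
    re-broadcast every ``policy.baseline_relaunch`` seconds (driven by the
    simulator; this function performs one broadcast).
    """
    space = plan.space(call.origin_space)
    if not space.has_fixed_button:
        call.impossible = True
        return DispatchDecision(
            call_id=call.sequence_number,
            stage=DispatchStage.IMPOSSIBLE,
            clock=kb.clock,
        )
    patient = kb.get_patient(call.patient) if call.patient else None
    department = (
        patient.department
        if patient is not None
        else (space.department or next(iter(kb.departments)))
    )
    nurses = kb.nurses_of_department(department)
    recipients = frozenset(n.id for n in nurses if n.id != call.maker)
    if not recipients:
        raise NoCandidateError(f"department {department!r} has no nurses")
    call.broadcast_set = set(recipients)
    return DispatchDecision(
        call_id=call.sequence_number,
        stage=DispatchStage.BROADCAST,
        clock=kb.clock,
        broadcast_set=recipients,
    )


def decide_interrupt(
    staff: StaffMember,
    incoming_priority: Optional[PriorityLevel],
    policy: PolicyConfig,
    rng,
) -> bool:
    """Should a busy staff member interrupt for an incoming call?

    With known priorities: interrupt a non-call task iff the incoming
    priority is higher or equal; interrupt a call being handled only for a
    strictly higher priority. Without a priority (place-oriented baseline)
    the choice is a Bernoulli draw from the provided generator.
    """
    if staff.current_task is None:
        raise WardCallError(f"{staff.id} is free; no interruption decision")
    if incoming_priority is None:
        return bool(rng.random() < policy.baseline_interrupt_probability)
    current = staff.current_task
    if current.kind is TaskKind.CALL_HANDLING:
        return incoming_priority > current.priority
    return incoming_priority >= current.priority
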