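"""Core domain model: calls, tasks, patients, staff and the ward knowledge base.

The model mirrors the profile/call ontology of a person-oriented nurse-call
system: patients carry risk factors and preferred helper characteristics,
staff members carry roles, characteristics, responsibilities and a current
task, and calls walk a small status machine
(``active -> answered -> busy -> finished``) while the dispatch layer picks
an assignee.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Optional

from .errors import (
    IllegalTransitionError,
    RoleError,
    UnknownEntityError,
    WardCallError,
)

# ---------------------------------------------------------------------------
# Probability intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=False)
class ProbabilityInterval:
    """Closed interval ``[lower, upper]`` inside [0, 1].

    All probabilistic knowledge in the priority engine is carried by these
    intervals: e.g. "a diabetic patient has at least 50% chance of being a
    high-risk patient" is ``ProbabilityInterval(0.5, 1.0)``.
    """

    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(
                f"invalid probability interval [{self.lower}, {self.upper}]"
            )

    def __iter__(self):
        yield self.lower
        yield self.upper

    def contains(self, other: "ProbabilityInterval") -> bool:
        return self.lower <= other.lower and other.upper <= self.upper

    @classmethod
    def point(cls, p: float) -> "ProbabilityInterval":
        return cls(p, p)


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------


class PriorityLevel(IntEnum):
    """Seven ordered urgency classes; larger value = more urgent."""

    LOWEST = 1
    LOW = 2
    BELOW_NORMAL = 3
    NORMAL = 4
    ABOVE_NORMAL = 5
    HIGH = 6
    HIGHEST = 7


#: Priority levels ordered Highest -> Lowest, the order in which the
#: threshold algorithm walks levels and in which 7-vectors are laid out.
PRIORITY_DESC = tuple(sorted(PriorityLevel, reverse=True))


class RiskFactor(str, Enum):
    HIGH_AGE = "high_age"
    DIABETES = "diabetes"
    HEART_DISEASE = "heart_disease"
    HIGH_FALL_RISK = "high_fall_risk"
    NEUROLOGIC_PROBLEM = "neurologic_problem"
    TRACHEOTOMY = "tracheotomy"
    COPD = "copd"
    PARAPLEGIA = "paraplegia"
    PNEUMONIA = "pneumonia"
    DISORIENTED_CONFUSED = "disoriented_confused"
    GASTRIC_BLEEDING_48H = "gastric_bleeding_48h"
    TRANSFERRED_FROM_ICU = "transferred_from_icu"
    TRANSFERRED_FROM_ICU_72H = "transferred_from_icu_72h"
    REANIMATED = "reanimated"
    REANIMATED_72H = "reanimated_72h"


class CallKind(str, Enum):
    NORMAL = "normal"
    SANITARY = "sanitary"
    SERVICE = "service"
    ASSISTANCE = "assistance"
    SANITARY_ASSISTANCE = "sanitary_assistance"
    URGENCY = "urgency"
    MEDICAL = "medical"
    TECHNICAL = "technical"


#: Call kinds launched by patients (sanitary kinds arise by transformation).
PATIENT_CALL_KINDS = frozenset(
    {CallKind.NORMAL, CallKind.SANITARY, CallKind.SERVICE}
)


class CallStatus(str, Enum):
    ACTIVE = "active"
    ANSWERED = "answered"
    BUSY = "busy"
    FINISHED = "finished"


class Role(str, Enum):
    NURSE = "nurse"
    HEAD_NURSE = "head_nurse"
    INTERN = "intern"
    CARETAKER = "caretaker"
    SANITARY_HELPER = "sanitary_helper"
    FAMILY_CAREGIVER = "family_caregiver"
    DOCTOR = "doctor"
    TECHNICAL_STAFF = "technical_staff"
    DEVICE = "device"  # pseudo-staff for device-launched technical calls


#: Roles counted as medical staff (candidates for urgency calls).
MEDICAL_ROLES = frozenset(
    {Role.NURSE, Role.INTERN, Role.CARETAKER, Role.DOCTOR}
)


class TaskKind(str, Enum):
    CALL_HANDLING = "call_handling"
    OTHER = "other"


class Interruptible(str, Enum):
    ALWAYS = "always"
    SOMETIMES = "sometimes"
    NEVER = "never"


def interruptible_class_for(priority: PriorityLevel) -> Interruptible:
    """Interruptibility implied by a task's priority.

    Low/Lowest tasks are always interruptible, High tasks never,
    the middle band sometimes.
    """
    if priority in (PriorityLevel.LOW, PriorityLevel.LOWEST):
        return Interruptible.ALWAYS
    if priority in (PriorityLevel.HIGH, PriorityLevel.HIGHEST):
        return Interruptible.NEVER
    return Interruptible.SOMETIMES


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------


@dataclass
class Task:
    id: str
    kind: TaskKind
    priority: PriorityLevel
    patient: Optional[str] = None
    deadline: Optional[int] = None
    call_id: Optional[int] = None  # set for call_handling tasks
    duration: int = 0  # seconds, simulator bookkeeping
    remaining: int = 0
    location: Optional[str] = None

    @property
    def interruptible_class(self) -> Interruptible:
        return interruptible_class_for(self.priority)


@dataclass
class Patient:
    id: str
    bed: str = ""
    room: str = ""
    department: str = "dept"
    risk_factors: set = field(default_factory=set)
    preferred_characteristics: set = field(default_factory=set)
    current_location: str = ""
    mobile: bool = True


@dataclass
class StaffMember:
    id: str
    role: Role = Role.NURSE
    departments: set = field(default_factory=set)
    characteristics: set = field(default_factory=set)
    refuses_patients: set = field(default_factory=set)
    responsible_for: set = field(default_factory=set)
    current_location: str = ""
    current_task: Optional[Task] = None
    task_queue: list = field(default_factory=list)

    @property
    def free(self) -> bool:
        return self.current_task is None


@dataclass
class Call:
    sequence_number: int
    kind: CallKind
    status: CallStatus = CallStatus.ACTIVE
    maker: str = ""
    patient: Optional[str] = None
    origin_space: str = ""
    priority: Optional[PriorityLevel] = None
    priority_bounds: Optional[tuple] = None  # 7 ProbabilityIntervals, Highest->Lowest
    timeout: int = 180
    t_launched: Optional[int] = None
    t_answered: Optional[int] = None
    t_staff_arrived: Optional[int] = None
    t_finished: Optional[int] = None
    assignee: Optional[str] = None
    broadcast_set: Optional[set] = None
    relaunch_count: int = 0
    impossible: bool = False
    excluded: set = field(default_factory=set)  # staff excluded after time-outs


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


class KnowledgeBase:
    """Mutable in-memory ward state: entities, calls and the clock."""

    def __init__(self):
        self.patients: dict[str, Patient] = {}
        self.staff: dict[str, StaffMember] = {}
        self.departments: set[str] = set()
        self.calls: dict[int, Call] = {}
        self.clock: int = 0
        self._seq = itertools.count(1)

    # -- registration -------------------------------------------------

    def add_patient(self, patient: Patient) -> Patient:
        self.patients[patient.id] = patient
        self.departments.add(patient.department)
        return patient

    def add_staff(self, member: StaffMember) -> StaffMember:
        self.staff[member.id] = member
        self.departments.update(member.departments)
        return member

    def next_sequence_number(self) -> int:
        return next(self._seq)

    # -- lookups ------------------------------------------------------

    def get_patient(self, patient_id: str) -> Patient:
        try:
            return self.patients[patient_id]
        except KeyError:
            raise UnknownEntityError(f"unknown patient {patient_id!r}") from None

    def get_staff(self, staff_id: str) -> StaffMember:
        try:
            return self.staff[staff_id]
        except KeyError:
            raise UnknownEntityError(f"unknown staff member {staff_id!r}") from None

    def responsible_nurse(self, patient_id: str) -> Optional[StaffMember]:
        for member in self.staff.values():
            if patient_id in member.responsible_for:
                return member
        return None

    def nurses_of_department(self, department: str) -> list[StaffMember]:
        """Dispatchable nurses of a department (head nurse never included)."""
        return [
            s
            for s in self.staff.values()
            if s.role is Role.NURSE and department in s.departments
        ]

    def validate(self) -> None:
        """Referential integrity plus the one-responsible-nurse partition."""
        seen: dict[str, str] = {}
        for member in self.staff.values():
            for pid in member.responsible_for:
                if pid not in self.patients:
                    raise UnknownEntityError(
                        f"{member.id} responsible for unknown patient {pid!r}"
                    )
                if pid in seen:
                    raise WardCallError(
                        f"patient {pid!r} assigned to both {seen[pid]} and {member.id}"
                    )
                seen[pid] = member.id
        for call in self.calls.values():
            if call.assignee is not None and call.assignee not in self.staff:
                raise UnknownEntityError(
                    f"call {call.sequence_number} assigned to unknown staff"
                )

    def to_json(self) -> dict:
        """JSON-serializable snapshot keyed by entity id."""

        def _tags(values: Iterable) -> list:
            return sorted(str(v) for v in values)

        return {
            "clock": self.clock,
            "patients": {
                p.id: {
                    "bed": p.bed,
                    "room": p.room,
                    "department": p.department,
                    "risk_factors": _tags(f.value for f in p.risk_factors),
                    "preferred_characteristics": _tags(p.preferred_characteristics),
                    "current_location": p.current_location,
                    "mobile": p.mobile,
                }
                for p in self.patients.values()
            },
            "staff": {
                s.id: {
                    "role": s.role.value,
                    "departments": _tags(s.departments),
                    "characteristics": _tags(s.characteristics),
                    "refuses_patients": _tags(s.refuses_patients),
                    "responsible_for": _tags(s.responsible_for),
                    "current_location": s.current_location,
                }
                for s in self.staff.values()
            },
            "calls": {
                str(c.sequence_number): {
                    "kind": c.kind.value,
                    "status": c.status.value,
                    "maker": c.maker,
                    "origin_space": c.origin_space,
                    "priority": c.priority.name if c.priority else None,
                    "t_launched": c.t_launched,
                    "t_answered": c.t_answered,
                    "t_staff_arrived": c.t_staff_arrived,
                    "t_finished": c.t_finished,
                    "assignee": c.assignee,
                    "impossible": c.impossible,
                    "relaunch_count": c.relaunch_count,
                }
                for c in self.calls.values()
            },
        }


# ---------------------------------------------------------------------------
# Call-kind rules
# ---------------------------------------------------------------------------

#: Roles allowed to launch each call kind.
LAUNCHER_ROLES: dict[CallKind, frozenset] = {
    CallKind.NORMAL: frozenset({"patient"}),
    CallKind.SANITARY: frozenset({"patient"}),
    CallKind.SERVICE: frozenset({"patient"}),
    CallKind.ASSISTANCE: frozenset({Role.NURSE, Role.INTERN, Role.HEAD_NURSE}),
    CallKind.SANITARY_ASSISTANCE: frozenset(
        {Role.NURSE, Role.INTERN, Role.HEAD_NURSE}
    ),
    CallKind.URGENCY: frozenset({Role.NURSE, Role.INTERN, Role.HEAD_NURSE}),
    CallKind.MEDICAL: frozenset({Role.NURSE, Role.INTERN, Role.HEAD_NURSE}),
    CallKind.TECHNICAL: frozenset(
        {Role.NURSE, Role.INTERN, Role.HEAD_NURSE, Role.DEVICE}
    ),
}


def allowed_handlers(kind: CallKind) -> frozenset:
    """Set of staff roles that may answer a call of the given kind.

    Normal, sanitary and (sanitary) assistance calls are nurse calls (interns
    count as nurses); service calls may additionally go to caretakers;
    medical calls go to doctors, technical calls to technical staff, and
    urgency calls to any medical staff member.
    """
    kind = CallKind(kind)
    if kind in (
        CallKind.NORMAL,
        CallKind.SANITARY,
        CallKind.ASSISTANCE,
        CallKind.SANITARY_ASSISTANCE,
    ):
        return frozenset({Role.NURSE, Role.INTERN})
    if kind is CallKind.SERVICE:
        return frozenset({Role.NURSE, Role.INTERN, Role.CARETAKER})
    if kind is CallKind.MEDICAL:
        return frozenset({Role.DOCTOR})
    if kind is CallKind.TECHNICAL:
        return frozenset({Role.TECHNICAL_STAFF})
    if kind is CallKind.URGENCY:
        return MEDICAL_ROLES
    raise RoleError(f"unknown call kind {kind!r}")


def classify_call_kind(requested_kind: CallKind, origin_space) -> CallKind:
    """Transform a requested call kind based on where it was made.

    A normal call made inside a sanitary space becomes a sanitary call; an
    assistance call made inside a sanitary space becomes a sanitary
    assistance call. Everything else passes through unchanged.
    ``origin_space`` is a floor-plan ``Space`` (anything with a ``kind``
    attribute whose value may be ``"sanitary"``).
    """
    requested_kind = CallKind(requested_kind)
    space_kind = getattr(origin_space, "kind", None)
    if space_kind is None:
        raise UnknownEntityError(f"unknown space {origin_space!r}")
    sanitary = str(getattr(space_kind, "value", space_kind)) == "sanitary"
    if sanitary and requested_kind is CallKind.NORMAL:
        return CallKind.SANITARY
    if sanitary and requested_kind is CallKind.ASSISTANCE:
        return CallKind.SANITARY_ASSISTANCE
    return requested_kind


def launch_call(
    kb: KnowledgeBase,
    maker_id: str,
    requested_kind: CallKind,
    origin_space,
    clock: Optional[int] = None,
    patient_id: Optional[str] = None,
    timeout: int = 180,
) -> Call:
    """Create a new active call in the knowledge base.

    ``origin_space`` is the floor-plan Space the maker is in; the call kind
    is re-classified according to it. ``patient_id`` identifies the patient
    the call is about; defaults to the maker when the maker is a patient.
    """
    requested_kind = CallKind(requested_kind)
    clock = kb.clock if clock is None else clock
    allowed = LAUNCHER_ROLES[requested_kind]
    if maker_id in kb.patients:
        if "patient" not in allowed:
            raise RoleError(
                f"patients may not launch {requested_kind.value} calls"
            )
        patient_id = patient_id or maker_id
    elif maker_id in kb.staff:
        role = kb.get_staff(maker_id).role
        if role not in allowed:
            raise RoleError(
                f"role {role.value} may not launch {requested_kind.value} calls"
            )
    else:
        raise UnknownEntityError(f"unknown call maker {maker_id!r}")

    kind = classify_call_kind(requested_kind, origin_space)
    call = Call(
        sequence_number=kb.next_sequence_number(),
        kind=kind,
        status=CallStatus.ACTIVE,
        maker=maker_id,
        patient=patient_id,
        origin_space=getattr(origin_space, "id", origin_space),
        t_launched=clock,
        timeout=timeout,
    )
    kb.calls[call.sequence_number] = call
    return call


_LEGAL_TRANSITIONS = {
    CallStatus.ACTIVE: {CallStatus.ACTIVE, CallStatus.ANSWERED},
    CallStatus.ANSWERED: {CallStatus.BUSY, CallStatus.ACTIVE},
    CallStatus.BUSY: {CallStatus.FINISHED, CallStatus.ACTIVE},
    CallStatus.FINISHED: set(),
}


def set_status(
    kb: KnowledgeBase, call: Call, new_status: CallStatus, clock: Optional[int] = None
) -> Call:
    """Advance a call through its status machine, recording timestamps.

    active -> answered (a staff member has been called), answered -> busy
    (treatment started; the assignee's current task becomes the call),
    busy -> finished (the assignee pops its task queue). Re-activation
    (answered/busy -> active) supports time-outs and interruptions;
    active -> active is a relaunch.
    """
    new_status = CallStatus(new_status)
    clock = kb.clock if clock is None else clock
    if new_status not in _LEGAL_TRANSITIONS[call.status]:
        raise IllegalTransitionError(
            f"call {call.sequence_number}: {call.status.value} -> {new_status.value}"
        )
    old = call.status
    call.status = new_status
    if new_status is CallStatus.ANSWERED:
        call.t_answered = clock
    elif new_status is CallStatus.ACTIVE and old is CallStatus.ACTIVE:
        call.relaunch_count += 1
    elif new_status is CallStatus.BUSY:
        call.t_staff_arrived = clock
        if call.assignee is not None:
            member = kb.get_staff(call.assignee)
            member.current_task = Task(
                id=f"call-{call.sequence_number}",
                kind=TaskKind.CALL_HANDLING,
                priority=call.priority or PriorityLevel.NORMAL,
                patient=call.patient,
                call_id=call.sequence_number,
            )
    elif new_status is CallStatus.FINISHED:
        call.t_finished = clock
        if call.assignee is not None:
            member = kb.get_staff(call.assignee)
            if (
                member.current_task is not None
                and member.current_task.call_id == call.sequence_number
            ):
                member.current_task = (
                    member.task_queue.pop(0) if member.task_queue else None
                )
    return call


class InterruptOutcome(str, Enum):
    TASK_QUEUED = "task_queued"
    CALL_REASSIGNED = "call_reassigned"


def interrupt_task(kb: KnowledgeBase, staff: StaffMember, incoming_call: Call):
    """Interrupt a busy staff member's current task for an accepted call.

    A non-call task is pushed onto the member's task queue (never lost);
    a call being handled reverts to active so another staff member can be
    searched for it. Returns the outcome and, for a reassigned call, the
    call object that went back to active.
    """
    if staff.current_task is None:
        raise WardCallError(f"{staff.id} is free; nothing to interrupt")
    task = staff.current_task
    staff.current_task = None
    if task.kind is TaskKind.CALL_HANDLING and task.call_id is not None:
        old_call = kb.calls[task.call_id]
        old_call.assignee = None
        old_call.status = CallStatus.ACTIVE
        return InterruptOutcome.CALL_REASSIGNED, old_call
    staff.task_queue.insert(0, task)
    return InterruptOutcome.TASK_QUEUED, None
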