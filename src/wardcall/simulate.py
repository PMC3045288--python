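"""Discrete-event ward simulator.

A synchronous tick engine (default tick = 5 s). Per tick: patients move
between spaces according to a time budget and launch calls per a Bernoulli
approximation of a Poisson process; a calling patient stands still. Calls
are classified, prioritized (person-oriented policy only) and dispatched
per the active policy; staff walk at a constant speed, arrival starts
treatment, completion finishes the call. Nurses handling a call launch
assistance calls at a small per-tick rate. Time-outs (person-oriented) and
180-s relaunches (place-oriented) fire as configured.

All randomness flows from one seed through named substreams, so the
generated call schedule and patient itineraries are identical between the
two policies of a paired comparison (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .dispatch import (
    DispatchStage,
    PolicyConfig,
    decide_interrupt,
    on_timeout,
    oncs_select,
    place_oriented_dispatch,
)
from .errors import ConfigError, NoCandidateError
from .floorplan import FloorPlan, Position, advance, start_walk
from .model import (
    Call,
    CallKind,
    CallStatus,
    KnowledgeBase,
    PriorityLevel,
    Role,
    StaffMember,
    Task,
    TaskKind,
    launch_call,
    set_status,
)
from .priority import assign_priority, assign_risk_groups, priority_bounds
from .scenario import Scenario, assign_responsibilities, generate_staff

POLICIES = ("person", "place")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class BehaviorConfig:
    """Patient and nurse behavior parameters.

    ``call_rate`` is the per-patient per-tick probability of launching a
    call; ``assistance_rate`` the per-tick probability that a nurse
    handling a call launches an assistance call. Walking speed is
    ``step_meters`` per tick (defaults give 1 m/s at 5-s ticks).
    """

    call_rate: float = defaults.DEFAULT_CALL_RATE
    assistance_rate: float = defaults.DEFAULT_ASSISTANCE_RATE
    tick_seconds: int = 5
    step_meters: float = 5.0
    task_mix: dict = field(default_factory=lambda: dict(defaults.DEFAULT_TASK_MIX))
    call_reason_mix: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_CALL_REASON_MIX)
    )
    patient_space_budget: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_PATIENT_SPACE_BUDGET)
    )
    dwell_means: dict = field(default_factory=lambda: dict(defaults.DEFAULT_DWELL_MEANS))
    duration_sigma: float = 0.5  # lognormal shape for service/task durations
    impossible_giveup_s: int = 300  # how long a patient waits on an unanswerable call

    def __post_init__(self):
        for name in ("call_rate", "assistance_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.tick_seconds <= 0 or self.step_meters <= 0:
            raise ConfigError("tick_seconds and step_meters must be positive")
        shares = sum(share for share, *_ in self.task_mix.values())
        if abs(shares - 1.0) > 1e-9:
            raise ConfigError(f"task_mix shares sum to {shares}, not 1")
        probs = sum(p for p, *_ in self.call_reason_mix.values())
        if abs(probs - 1.0) > 1e-9:
            raise ConfigError(f"call_reason_mix probabilities sum to {probs}, not 1")


@dataclass(frozen=True)
class ShiftSpec:
    """One rostered shift: ``("week"|"weekend", "early"|"late"|"night")``."""

    week_part: str
    name: str
    nurse_count: int
    duration_ticks: int

    @property
    def key(self) -> tuple:
        return (self.week_part, self.name)


ALL_SHIFT_KEYS = (
    ("week", "early"),
    ("week", "late"),
    ("week", "night"),
    ("weekend", "early"),
    ("weekend", "late"),
    ("weekend", "night"),
)


def make_shift(
    scenario: Scenario, key: tuple, behavior: BehaviorConfig, hours: float = 8.0
) -> ShiftSpec:
    return ShiftSpec(
        week_part=key[0],
        name=key[1],
        nurse_count=int(scenario.config.shift_roster[tuple(key)]),
        duration_ticks=int(round(hours * 3600 / behavior.tick_seconds)),
    )


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

EVENT_COLUMNS = (
    "tick",
    "event",
    "call_id",
    "staff_id",
    "patient_id",
    "space_id",
    "call_kind",
    "priority",
    "stage",
    "policy",
)


@dataclass
class EventLog:
    policy: str
    seed: int
    shift: tuple
    n_nurses: int
    n_patients: int
    tick_seconds: int
    duration_ticks: int
    records: list = field(default_factory=list)

    def append(self, tick, event, call=None, staff_id=None, patient_id=None,
               space_id=None, priority=None, stage=None):
        self.records.append(
            (
                tick,
                event,
                call.sequence_number if call is not None else None,
                staff_id,
                patient_id,
                space_id,
                call.kind.value if call is not None else None,
                priority.name if priority is not None else None,
                stage.value if stage is not None else None,
                self.policy,
            )
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=EVENT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        policy = str(df["policy"].iloc[0]) if len(df) else "person"
        nurse_ids = {
            s for s in df["staff_id"].dropna().astype(str) if s.startswith("n")
        }
        log = cls(
            policy=policy, seed=-1, shift=("?", "?"), n_nurses=len(nurse_ids),
            n_patients=0, tick_seconds=5,
            duration_ticks=int(df["tick"].max()) + 1 if len(df) else 0,
        )
        log.records = [tuple(None if pd.isna(v) else v for v in row)
                       for row in df.itertuples(index=False)]
        return log


# ---------------------------------------------------------------------------
# Simulation engine
# ---------------------------------------------------------------------------


@dataclass
class _PatientState:
    patient: object
    position: Position
    dwell_until: int = 0
    open_call: Optional[int] = None
    move_rng: object = None


@dataclass
class _NurseState:
    member: StaffMember
    position: Position
    # walking target: call origin space or task location
    walking_to: Optional[str] = None
    current_call: Optional[int] = None  # call committed to (walking or treating)
    treating: bool = False
    treat_until: int = 0
    task_started: bool = False
    task_until: int = 0
    pending_calls: set = field(default_factory=set)
    assistance_requested: set = field(default_factory=set)  # calls already escalated


@dataclass
class _CallState:
    call: Call
    duration_s: int
    remaining_s: int = -1  # unstarted; set to duration_s on first treatment
    accepted: bool = False
    timeout_tick: Optional[int] = None
    responders: set = field(default_factory=set)  # place policy
    treated_by: Optional[str] = None
    first_arrival_tick: Optional[int] = None


class ShiftSimulation:
    """One shift of one policy on a concrete scenario instance."""

    def __init__(
        self,
        scenario: Scenario,
        policy_name: str,
        shift: ShiftSpec,
        behavior: BehaviorConfig,
        seed: int,
        policy: Optional[PolicyConfig] = None,
    ):
        if policy_name not in POLICIES:
            raise ConfigError(f"unknown policy {policy_name!r}; use one of {POLICIES}")
        self.scenario = scenario
        self.policy_name = policy_name
        self.shift = shift
        self.behavior = behavior
        self.policy = policy or PolicyConfig()
        self.seed = int(seed)
        self.plan = scenario.plan

        shift_idx = (
            ALL_SHIFT_KEYS.index(shift.key) if shift.key in ALL_SHIFT_KEYS else 7
        )
        ss = np.random.SeedSequence([self.seed, shift_idx])
        # fixed spawn order: schedule, staff-roster, patient-movement,
        # nurse-tasks, policy decisions
        (s_sched, s_staff, s_moves, s_tasks, s_policy) = ss.spawn(5)
        self.rng_schedule = np.random.default_rng(s_sched)
        self.rng_staff = np.random.default_rng(s_staff)
        self.rng_tasks = np.random.default_rng(s_tasks)
        self.rng_policy = np.random.default_rng(s_policy)

        self.kb = KnowledgeBase()
        for p in scenario.patients:
            self.kb.add_patient(p)
        roster_cfg = dict(scenario.config.shift_roster)
        roster_cfg[shift.key] = shift.nurse_count
        cfg = scenario.config
        cfg_roster_backup = cfg.shift_roster
        cfg.shift_roster = roster_cfg
        staff = generate_staff(cfg, shift.key, self.rng_staff)
        cfg.shift_roster = cfg_roster_backup
        for s in staff:
            self.kb.add_staff(s)
        nurses = [s for s in staff if s.role is Role.NURSE]
        assign_responsibilities(scenario.patients, nurses)

        move_streams = np.random.default_rng(s_moves).spawn(len(scenario.patients))
        self.patients = {
            p.id: _PatientState(
                patient=p,
                position=Position(space=p.room),
                dwell_until=0,
                move_rng=mr,
            )
            for p, mr in zip(scenario.patients, move_streams)
        }
        for p in scenario.patients:
            p.current_location = p.room
        self.nurses = {
            n.id: _NurseState(member=n, position=Position(space=n.current_location))
            for n in nurses
        }
        self.calls: dict[int, _CallState] = {}
        self.log = EventLog(
            policy=policy_name,
            seed=self.seed,
            shift=shift.key,
            n_nurses=shift.nurse_count,
            n_patients=len(scenario.patients),
            tick_seconds=behavior.tick_seconds,
            duration_ticks=shift.duration_ticks,
        )
        self.schedule = self._pregenerate_schedule()
        self.tick = 0

    # -- schedule -----------------------------------------------------

    def _pregenerate_schedule(self) -> dict:
        """Per patient: list of (tick, reason, requested kind, duration s).

        Pre-generated from a policy-independent stream so paired policies
        see the same calls.
        """
        b = self.behavior
        reasons = list(b.call_reason_mix)
        probs = np.asarray([b.call_reason_mix[r][0] for r in reasons])
        schedule: dict[str, list] = {}
        for pid in sorted(self.patients):
            hits = np.flatnonzero(
                self.rng_schedule.random(self.shift.duration_ticks) < b.call_rate
            )
            entries = []
            for t in hits:
                reason = reasons[self.rng_schedule.choice(len(reasons), p=probs)]
                _, mean_dur, kind = b.call_reason_mix[reason]
                dur = self._lognormal_duration(self.rng_schedule, mean_dur)
                entries.append((int(t), reason, CallKind(kind), dur))
            schedule[pid] = entries
        return schedule

    def _lognormal_duration(self, rng, mean_s: float) -> int:
        sigma = self.behavior.duration_sigma
        mu = math.log(mean_s) - sigma * sigma / 2.0
        return max(1, int(round(rng.lognormal(mu, sigma))))

    # -- helpers ------------------------------------------------------

    @property
    def clock(self) -> int:
        return self.tick * self.behavior.tick_seconds

    def _ticks(self, seconds: float) -> int:
        return max(1, math.ceil(seconds / self.behavior.tick_seconds))

    def _sanitary_of(self, room: str) -> Optional[str]:
        candidate = room.replace("room_", "sanitary_")
        return candidate if candidate in self.plan.spaces else None

    # -- main loop ----------------------------------------------------

    def run(self) -> EventLog:
        for self.tick in range(self.shift.duration_ticks):
            self.kb.clock = self.clock
            self._step_patients()
            self._launch_scheduled_calls()
            self._step_nurses()
            if self.policy_name == "person":
                self._fire_timeouts()
            else:
                self._fire_relaunches()
        return self.log

    # -- patients -----------------------------------------------------

    def _step_patients(self):
        b = self.behavior
        for pid in sorted(self.patients):
            st = self.patients[pid]
            call_state = self.calls.get(st.open_call) if st.open_call else None
            if call_state is not None:
                done = call_state.call.status is CallStatus.FINISHED
                gave_up = (
                    call_state.call.impossible
                    and self.clock - call_state.call.t_launched
                    >= b.impossible_giveup_s
                )
                if done or gave_up:
                    st.open_call = None
                    st.dwell_until = self.tick  # re-decide where to go
                else:
                    continue  # a calling patient stands still
            pos = st.position
            if pos.target is not None:
                pos = st.position = advance(self.plan, pos, pos.target, b.step_meters)
                st.patient.current_location = pos.space
                if pos.target is None:  # just arrived
                    category = self._category_of(pos.space, st)
                    mean = b.dwell_means.get(category, 600)
                    st.dwell_until = self.tick + self._ticks(
                        st.move_rng.exponential(mean)
                    )
                    self.log.append(
                        self.tick, "moved", patient_id=pid, space_id=pos.space
                    )
                continue
            if self.tick < st.dwell_until:
                continue
            dest = self._choose_destination(st)
            if dest is None or dest == pos.space:
                st.dwell_until = self.tick + self._ticks(
                    st.move_rng.exponential(b.dwell_means.get("own_room", 600))
                )
                continue
            st.position = start_walk(self.plan, pos.space, dest)

    def _category_of(self, space_id: str, st: _PatientState) -> str:
        if space_id == st.patient.room:
            return "own_room"
        if space_id.startswith("sanitary"):
            return "sanitary"
        if space_id.startswith("corridor"):
            return "corridor"
        return space_id  # remote spaces keyed by their own id

    def _choose_destination(self, st: _PatientState) -> Optional[str]:
        budget = self.behavior.patient_space_budget
        cats = list(budget)
        p = np.asarray([budget[c] for c in cats], dtype=float)
        cat = cats[st.move_rng.choice(len(cats), p=p / p.sum())]
        if cat == "own_room":
            return st.patient.room
        if cat == "sanitary":
            return self._sanitary_of(st.patient.room)
        if cat == "corridor":
            corridors = [s for s in self.plan.spaces if s.startswith("corridor")]
            if not corridors:
                return None
            return corridors[st.move_rng.choice(len(corridors))]
        return cat if cat in self.plan.spaces else None

    # -- call launching -----------------------------------------------

    def _launch_scheduled_calls(self):
        for pid in sorted(self.patients):
            st = self.patients[pid]
            entries = self.schedule[pid]
            while entries and entries[0][0] <= self.tick:
                _, reason, kind, duration = entries.pop(0)
                if st.open_call is not None:
                    continue  # still waiting on the previous call
                self._launch_patient_call(st, kind, duration)

    def _launch_patient_call(self, st: _PatientState, kind: CallKind, duration: int):
        space = self.plan.space(st.position.space)
        call = launch_call(
            self.kb,
            st.patient.id,
            kind,
            space,
            clock=self.clock,
            timeout=self.policy.timeouts.get(kind, 180),
        )
        st.open_call = call.sequence_number
        self.calls[call.sequence_number] = _CallState(call=call, duration_s=duration)
        self.log.append(
            self.tick, "call_launched", call=call, patient_id=st.patient.id,
            space_id=space.id,
        )
        self._prioritize_and_dispatch(call)

    def _launch_assistance_call(self, nurse: _NurseState, treated_patient_id: str):
        space = self.plan.space(nurse.position.space)
        call = launch_call(
            self.kb,
            nurse.member.id,
            CallKind.ASSISTANCE,
            space,
            clock=self.clock,
            patient_id=treated_patient_id,
            timeout=self.policy.timeouts.get(CallKind.ASSISTANCE, 180),
        )
        _, mean_dur, _ = self.behavior.call_reason_mix.get(
            "toileting", (0, 300, "normal")
        )
        duration = self._lognormal_duration(self.rng_tasks, mean_dur)
        self.calls[call.sequence_number] = _CallState(call=call, duration_s=duration)
        self.log.append(
            self.tick, "call_launched", call=call, staff_id=nurse.member.id,
            patient_id=treated_patient_id, space_id=space.id,
        )
        self._prioritize_and_dispatch(call)

    def _prioritize_and_dispatch(self, call: Call):
        if self.policy_name == "person":
            patient = self.kb.get_patient(call.patient)
            assignment = assign_risk_groups(patient, self.scenario.risk_table)
            call.priority_bounds = priority_bounds(
                assignment, call.kind, self.scenario.priority_table
            )
            call.priority = assign_priority(
                call.priority_bounds, self.scenario.thresholds
            )
            self.log.append(
                self.tick, "priority_assigned", call=call,
                patient_id=call.patient, priority=call.priority,
            )
            self._person_dispatch(call)
        else:
            self._place_broadcast(call, first=True)

    # -- person-oriented dispatch ------------------------------------

    def _person_dispatch(self, call: Call):
        try:
            decision = oncs_select(call, self.kb, self.plan, self.policy)
        except NoCandidateError:
            return
        call.assignee = decision.assignee
        if call.status is CallStatus.ACTIVE:
            set_status(self.kb, call, CallStatus.ANSWERED, self.clock)
        self.log.append(
            self.tick, "dispatched", call=call, staff_id=decision.assignee,
            priority=call.priority, stage=decision.stage,
        )
        state = self.calls[call.sequence_number]
        state.timeout_tick = self.tick + self._ticks(call.timeout)
        nurse = self.nurses[decision.assignee]
        member = nurse.member
        if member.free:
            accept = True
        else:
            accept = decide_interrupt(member, call.priority, self.policy, self.rng_policy)
        if accept:
            self._nurse_accept(nurse, call)
        else:
            nurse.pending_calls.add(call.sequence_number)
            self.log.append(
                self.tick, "ignored", call=call, staff_id=member.id,
                priority=call.priority,
            )

    def _nurse_accept(self, nurse: _NurseState, call: Call):
        member = nurse.member
        old_task = member.current_task
        if (
            old_task is not None
            and old_task.kind is TaskKind.OTHER
            and nurse.task_started
        ):
            old_task.remaining = max(
                self.behavior.tick_seconds,
                (nurse.task_until - self.tick) * self.behavior.tick_seconds,
            )
        was_treating = nurse.treating
        # commit to the new call first so that re-dispatch of an interrupted
        # call sees this nurse as busy with the (higher-priority) newcomer
        state = self.calls[call.sequence_number]
        state.accepted = True
        nurse.pending_calls.discard(call.sequence_number)
        nurse.current_call = call.sequence_number
        nurse.treating = False
        nurse.task_started = False
        nurse.walking_to = call.origin_space
        member.current_task = Task(
            id=f"call-{call.sequence_number}",
            kind=TaskKind.CALL_HANDLING,
            priority=call.priority or PriorityLevel.NORMAL,
            patient=call.patient,
            call_id=call.sequence_number,
        )
        self.log.append(
            self.tick, "accepted", call=call, staff_id=member.id,
            priority=call.priority,
        )
        if old_task is not None:
            self._handle_interrupted_task(nurse, old_task, was_treating)

    def _handle_interrupted_task(self, nurse: _NurseState, task: Task,
                                 nurse_was_treating: bool = False):
        """Bookkeeping for the activity an accepted call displaced."""
        member = nurse.member
        if task.kind is TaskKind.CALL_HANDLING and task.call_id is not None:
            old_state = self.calls[task.call_id]
            old_call = old_state.call
            if old_call.sequence_number == nurse.current_call:
                return
            if old_state.treated_by is not None and old_state.treated_by != member.id:
                # someone else took over; this nurse merely stops walking
                old_state.responders.discard(member.id)
                return
            if old_state.treated_by == member.id and nurse_was_treating:
                old_state.remaining_s = max(
                    self.behavior.tick_seconds,
                    (nurse.treat_until - self.tick) * self.behavior.tick_seconds,
                )
            old_call.assignee = None
            old_state.accepted = False
            old_state.treated_by = None
            old_state.responders.discard(member.id)
            if old_call.status in (CallStatus.ANSWERED, CallStatus.BUSY):
                old_call.status = CallStatus.ACTIVE
            self.log.append(
                self.tick, "task_interrupted", call=old_call, staff_id=member.id,
                priority=old_call.priority,
            )
            if self.policy_name == "person" and old_call.status is CallStatus.ACTIVE:
                self._person_dispatch(old_call)
            # place policy: the call keeps its relaunch cadence
        else:
            # background task: remember the remainder, never lose it
            if task.remaining <= 0:
                task.remaining = task.duration
            self.log.append(
                self.tick, "task_interrupted", staff_id=member.id,
                patient_id=task.patient,
            )
            member.task_queue.insert(0, task)

    def _fire_timeouts(self):
        for state in list(self.calls.values()):
            call = state.call
            if (
                call.status is CallStatus.ANSWERED
                and not state.accepted
                and state.timeout_tick is not None
                and self.tick >= state.timeout_tick
            ):
                old = call.assignee
                if old is not None:
                    self.nurses[old].pending_calls.discard(call.sequence_number)
                try:
                    decision = on_timeout(
                        call, self.kb, self.plan, self.policy, self.clock
                    )
                except NoCandidateError:
                    state.timeout_tick = self.tick + self._ticks(call.timeout)
                    continue
                if decision is None:
                    continue
                self.log.append(
                    self.tick, "relaunched", call=call, staff_id=decision.assignee,
                    priority=call.priority, stage=decision.stage,
                )
                state.timeout_tick = self.tick + self._ticks(call.timeout)
                nurse = self.nurses[decision.assignee]
                member = nurse.member
                accept = member.free or decide_interrupt(
                    member, call.priority, self.policy, self.rng_policy
                )
                if accept:
                    self._nurse_accept(nurse, call)
                else:
                    nurse.pending_calls.add(call.sequence_number)
                    self.log.append(
                        self.tick, "ignored", call=call, staff_id=member.id,
                        priority=call.priority,
                    )

    # -- place-oriented dispatch --------------------------------------

    def _place_broadcast(self, call: Call, first: bool):
        state = self.calls[call.sequence_number]
        try:
            decision = place_oriented_dispatch(call, self.kb, self.policy, self.plan)
        except NoCandidateError:
            return
        if decision.stage is DispatchStage.IMPOSSIBLE:
            self.log.append(
                self.tick, "impossible_call", call=call,
                patient_id=call.patient, space_id=call.origin_space,
                stage=decision.stage,
            )
            return
        self.log.append(
            self.tick, "dispatched" if first else "relaunched", call=call,
            stage=decision.stage, space_id=call.origin_space,
        )
        if not first:
            call.relaunch_count += 1
        for nid in sorted(decision.broadcast_set):
            nurse = self.nurses.get(nid)
            if nurse is None or nid in state.responders:
                continue
            if nurse.current_call is not None and first:
                # committed to another call; such nurses reconsider only
                # when a waiting call is re-broadcast
                continue
            member = nurse.member
            if member.free:
                # a free nurse has no task to weigh the call against and
                # responds; ignoring is a decision about quitting a task
                respond = True
            else:
                respond = decide_interrupt(member, None, self.policy, self.rng_policy)
            if respond:
                self._baseline_respond(nurse, call)
            else:
                self.log.append(self.tick, "ignored", call=call, staff_id=nid)

    def _baseline_respond(self, nurse: _NurseState, call: Call):
        member = nurse.member
        old_task = member.current_task
        if (
            old_task is not None
            and old_task.kind is TaskKind.OTHER
            and nurse.task_started
        ):
            old_task.remaining = max(
                self.behavior.tick_seconds,
                (nurse.task_until - self.tick) * self.behavior.tick_seconds,
            )
        was_treating = nurse.treating
        if nurse.current_call is not None:
            old_state = self.calls[nurse.current_call]
            old_state.responders.discard(member.id)
        state = self.calls[call.sequence_number]
        state.responders.add(member.id)
        nurse.current_call = call.sequence_number
        nurse.treating = False
        nurse.task_started = False
        nurse.walking_to = call.origin_space
        member.current_task = Task(
            id=f"call-{call.sequence_number}",
            kind=TaskKind.CALL_HANDLING,
            priority=call.priority or PriorityLevel.NORMAL,
            patient=call.patient,
            call_id=call.sequence_number,
        )
        self.log.append(self.tick, "accepted", call=call, staff_id=member.id)
        if old_task is not None:
            self._handle_interrupted_task(nurse, old_task, was_treating)

    def _fire_relaunches(self):
        cadence = self._ticks(self.policy.baseline_relaunch)
        for state in list(self.calls.values()):
            call = state.call
            if call.impossible or call.status in (CallStatus.BUSY, CallStatus.FINISHED):
                continue
            if state.first_arrival_tick is not None and call.status is CallStatus.BUSY:
                continue
            launched_tick = int(call.t_launched // self.behavior.tick_seconds)
            elapsed = self.tick - launched_tick
            if elapsed > 0 and elapsed % cadence == 0 and state.treated_by is None:
                self._place_broadcast(call, first=False)

    # -- nurses ---------------------------------------------------------

    def _step_nurses(self):
        for nid in sorted(self.nurses):
            nurse = self.nurses[nid]
            member = nurse.member
            if nurse.current_call is not None and not nurse.treating:
                self._walk_to_call(nurse)
            elif nurse.treating:
                self._treat(nurse)
            elif nurse.walking_to is not None:
                self._walk_to_task(nurse)
            elif member.current_task is not None and nurse.task_started:
                if self.tick >= nurse.task_until:
                    member.current_task = None
                    nurse.task_started = False
            else:
                self._idle(nurse)
            member.current_location = nurse.position.space

    def _walk_to_call(self, nurse: _NurseState):
        call_id = nurse.current_call
        state = self.calls[call_id]
        call = state.call
        taken_by_other = call.status is CallStatus.FINISHED or (
            state.treated_by is not None and state.treated_by != nurse.member.id
        )
        if taken_by_other:
            # the call disappears from beepers once treatment starts (the
            # room light goes off); a racing nurse learns this one tick
            # later, so near-simultaneous arrivals still happen
            if self.policy_name != "place" or (
                state.first_arrival_tick is not None
                and state.first_arrival_tick < self.tick
            ):
                self._release_call(nurse)
                return
        target = call.origin_space
        nurse.position = advance(
            self.plan, nurse.position, target, self.behavior.step_meters
        )
        if nurse.position.space == target and nurse.position.target is None:
            self._arrive_at_call(nurse, state)

    def _arrive_at_call(self, nurse: _NurseState, state: _CallState):
        call = state.call
        member = nurse.member
        self.log.append(
            self.tick, "arrived", call=call, staff_id=member.id,
            space_id=call.origin_space, priority=call.priority,
        )
        already_treated = state.treated_by is not None or call.status in (
            CallStatus.BUSY,
            CallStatus.FINISHED,
        )
        if already_treated:
            self._release_call(nurse)
            return
        if state.first_arrival_tick is None:
            state.first_arrival_tick = self.tick
        state.treated_by = member.id
        call.assignee = member.id
        if call.status is CallStatus.ACTIVE:
            set_status(self.kb, call, CallStatus.ANSWERED, self.clock)
        set_status(self.kb, call, CallStatus.BUSY, self.clock)
        nurse.treating = True
        nurse.walking_to = None
        if state.remaining_s < 0:
            state.remaining_s = state.duration_s
        nurse.treat_until = self.tick + self._ticks(state.remaining_s)
        self.log.append(
            self.tick, "treatment_started", call=call, staff_id=member.id,
            space_id=call.origin_space, priority=call.priority,
        )

    def _release_call(self, nurse: _NurseState):
        """Arrived too late (or call withdrawn): log and go back to work."""
        call_id = nurse.current_call
        state = self.calls.get(call_id)
        if state is not None:
            state.responders.discard(nurse.member.id)
            if state.treated_by is not None and state.treated_by != nurse.member.id:
                self.log.append(
                    self.tick, "unnecessary_arrival", call=state.call,
                    staff_id=nurse.member.id, space_id=state.call.origin_space,
                )
        nurse.current_call = None
        nurse.treating = False
        nurse.walking_to = None
        member = nurse.member
        if member.current_task is not None and member.current_task.call_id == call_id:
            member.current_task = None
        self._resume(nurse)

    def _treat(self, nurse: _NurseState):
        state = self.calls[nurse.current_call]
        call = state.call
        if self.tick >= nurse.treat_until:
            set_status(self.kb, call, CallStatus.FINISHED, self.clock)
            self.log.append(
                self.tick, "treatment_finished", call=call,
                staff_id=nurse.member.id, priority=call.priority,
            )
            state.responders.discard(nurse.member.id)
            nurse.current_call = None
            nurse.treating = False
            # model pops the task queue into current_task on finish; hand it
            # to the walking logic below via _resume bookkeeping
            member = nurse.member
            if member.current_task is not None:
                task = member.current_task
                member.current_task = None
                member.task_queue.insert(0, task)
            self._resume(nurse)
            return
        if (
            self.behavior.assistance_rate > 0
            and call.kind in (CallKind.NORMAL, CallKind.SANITARY, CallKind.SERVICE)
            and call.sequence_number not in nurse.assistance_requested
        ):
            if self.rng_policy.random() < self.behavior.assistance_rate:
                nurse.assistance_requested.add(call.sequence_number)
                self._launch_assistance_call(nurse, call.patient)

    def _resume(self, nurse: _NurseState):
        """Pick the next activity: pending calls, queued tasks, then idle."""
        member = nurse.member
        if nurse.pending_calls:
            pending = [
                self.calls[cid].call
                for cid in nurse.pending_calls
                if self.calls[cid].call.status is CallStatus.ANSWERED
                and self.calls[cid].call.assignee == member.id
            ]
            nurse.pending_calls = {c.sequence_number for c in pending}
            if pending:
                chosen = nurse_choose_call(pending, member, self.plan)
                self._nurse_accept(nurse, chosen)
                return
        if member.task_queue:
            task = member.task_queue.pop(0)
            member.current_task = task
            nurse.task_started = False
            nurse.walking_to = task.location or nurse.position.space
            self.log.append(
                self.tick, "task_resumed", staff_id=member.id,
                patient_id=task.patient,
            )

    def _walk_to_task(self, nurse: _NurseState):
        member = nurse.member
        task = member.current_task
        if task is None:
            nurse.walking_to = None
            return
        target = nurse.walking_to
        nurse.position = advance(
            self.plan, nurse.position, target, self.behavior.step_meters
        )
        if nurse.position.space == target and nurse.position.target is None:
            nurse.walking_to = None
            nurse.task_started = True
            remaining = task.remaining if task.remaining > 0 else task.duration
            nurse.task_until = self.tick + self._ticks(remaining)

    def _idle(self, nurse: _NurseState):
        member = nurse.member
        if nurse.pending_calls or member.task_queue:
            self._resume(nurse)
            return
        b = self.behavior
        cats = list(b.task_mix)
        shares = np.asarray([b.task_mix[c][0] for c in cats], dtype=float)
        cat = cats[self.rng_tasks.choice(len(cats), p=shares / shares.sum())]
        _, mean_dur, prio_name = b.task_mix[cat]
        duration = self._lognormal_duration(self.rng_tasks, mean_dur)
        priority = PriorityLevel[prio_name]
        if cat in ("administration", "break"):
            location = "nursing_post" if "nursing_post" in self.plan.spaces else nurse.position.space
            patient = None
        else:
            rp = sorted(member.responsible_for)
            if rp:
                patient = rp[int(self.rng_tasks.integers(len(rp)))]
                location = self.kb.get_patient(patient).room
            else:
                patient, location = None, nurse.position.space
        task = Task(
            id=f"{member.id}-{cat}-{self.tick}",
            kind=TaskKind.OTHER,
            priority=priority,
            patient=patient,
            duration=duration,
            remaining=duration,
            location=location,
        )
        member.current_task = task
        nurse.task_started = False
        nurse.walking_to = location


def run_shift(
    scenario: Scenario,
    policy_name: str,
    shift: ShiftSpec,
    behavior: BehaviorConfig,
    seed: int,
    policy: Optional[PolicyConfig] = None,
) -> EventLog:
    """Simulate one shift under one policy; deterministic given the seed."""
    sim = ShiftSimulation(scenario, policy_name, shift, behavior, seed, policy)
    return sim.run()


# ---------------------------------------------------------------------------
# Call choice among several pending calls
# ---------------------------------------------------------------------------


def nurse_choose_call(pending: Sequence[Call], nurse: StaffMember, plan: FloorPlan) -> Call:
    """Pick among pending calls: highest priority, then closest, then first.

    Calls without a priority (place-oriented) rank below any prioritized
    call and are compared by distance and sequence number.
    """
    pending = list(pending)
    if not pending:
        raise ValueError("no pending calls to choose from")

    def key(call: Call):
        prio = int(call.priority) if call.priority is not None else 0
        dist = plan.distance(nurse.current_location, call.origin_space)
        return (-prio, dist, call.sequence_number)

    return min(pending, key=key)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def detect_unnecessary_arrivals(log: EventLog) -> int:
    """Arrivals at a call whose treatment another staff member already began.

    Recomputed from the raw event log: for every ``arrived`` event, check
    whether a ``treatment_started`` event for the same call happened at or
    before it with a different staff id.
    """
    df = log.to_dataframe()
    if df.empty:
        return 0
    count = 0
    relevant = df[df["event"].isin(["arrived", "treatment_started", "task_interrupted"])]
    for _, grp in relevant.groupby("call_id"):
        treating_staff = None  # staff currently (or last) treating the call
        for row in grp.itertuples(index=False):
            if row.event == "treatment_started":
                treating_staff = row.staff_id
            elif row.event == "task_interrupted":
                treating_staff = None  # treatment abandoned; next arrival is needed
            elif row.event == "arrived":
                if treating_staff is not None and row.staff_id != treating_staff:
                    count += 1
    return count


@dataclass
class Metrics:
    """Aggregated statistics over one or more identically configured runs."""

    policy: str
    arrival_delays: pd.DataFrame  # per answered call: run, kind, priority, delay_s
    workload: pd.DataFrame  # per run x nurse: handled, percent
    unnecessary_arrivals: int
    impossible_calls: int
    unanswered: int
    n_runs: int

    def workload_summary(self) -> pd.DataFrame:
        """Per run: Max., Min., # 0% and population std of nurse percentages."""
        rows = []
        for run, grp in self.workload.groupby("run"):
            pct = grp["percent"].to_numpy(dtype=float)
            rows.append(
                {
                    "run": run,
                    "n_nurses": len(pct),
                    "max": pct.max(),
                    "min": pct.min(),
                    "n_zero": int((pct == 0).sum()),
                    "std": float(np.sqrt(np.mean((pct - pct.mean()) ** 2))),
                }
            )
        return pd.DataFrame(rows)

    def arrival_histogram(self, by: Optional[str] = None) -> pd.DataFrame:
        """Two-regime histogram: 5-s bins up to 60 s, then 60-s bins."""
        return arrival_histogram(self.arrival_delays, by=by)


def arrival_histogram(delays: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    if delays.empty:
        return pd.DataFrame(columns=["group", "bin_start", "bin_end", "count"])
    max_delay = float(delays["delay_s"].max())
    edges = list(np.arange(0, 60, 5.0))
    top = max(60.0, math.ceil((max_delay + 1) / 60.0) * 60.0)
    edges += list(np.arange(60.0, top + 60.0, 60.0))
    frames = []
    groups = delays.groupby(by) if by else [("all", delays)]
    for name, grp in groups:
        counts, _ = np.histogram(grp["delay_s"].to_numpy(), bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "group": name if not isinstance(name, tuple) else "/".join(map(str, name)),
                    "bin_start": edges[:-1],
                    "bin_end": edges[1:],
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compute_metrics(logs: Sequence[EventLog]) -> Metrics:
    """Derive arrival-time, workload and incident statistics from event logs."""
    logs = list(logs)
    if not logs:
        raise ValueError("compute_metrics needs at least one event log")
    policy = logs[0].policy
    delay_rows = []
    workload_rows = []
    unnecessary = 0
    impossible = 0
    unanswered = 0
    for run, log in enumerate(logs):
        df = log.to_dataframe()
        tick_s = log.tick_seconds
        launched = df[df["event"] == "call_launched"].set_index("call_id")
        started = (
            df[df["event"] == "treatment_started"]
            .groupby("call_id")
            .agg(start_tick=("tick", "min"))
        )
        prio = (
            df[df["event"].isin(["priority_assigned", "dispatched"])]
            .dropna(subset=["priority"])
            .groupby("call_id")["priority"]
            .first()
            if not df.empty
            else pd.Series(dtype=object)
        )
        for call_id, row in launched.iterrows():
            if call_id in started.index:
                delay = (started.loc[call_id, "start_tick"] - row["tick"]) * tick_s
                delay_rows.append(
                    {
                        "run": run,
                        "call_id": call_id,
                        "kind": row["call_kind"],
                        "priority": prio.get(call_id),
                        "delay_s": float(delay),
                    }
                )
            else:
                unanswered += 1
        impossible += int((df["event"] == "impossible_call").sum()) if not df.empty else 0
        unnecessary += detect_unnecessary_arrivals(log)
        finished = df[df["event"] == "treatment_finished"]
        handled = finished.groupby("staff_id").size() if not finished.empty else pd.Series(dtype=int)
        total = int(handled.sum())
        nurse_ids = [f"n{i:02d}" for i in range(1, log.n_nurses + 1)]
        for nid in nurse_ids:
            h = int(handled.get(nid, 0))
            pct = 100.0 * h / total if total > 0 else 0.0
            workload_rows.append({"run": run, "staff_id": nid, "handled": h, "percent": pct})
    return Metrics(
        policy=policy,
        arrival_delays=pd.DataFrame(delay_rows),
        workload=pd.DataFrame(workload_rows),
        unnecessary_arrivals=unnecessary,
        impossible_calls=impossible,
        unanswered=unanswered,
        n_runs=len(logs),
    )


# ---------------------------------------------------------------------------
# Paired experiments
# ---------------------------------------------------------------------------


def run_experiment(
    scenario: Scenario,
    behavior: BehaviorConfig,
    seeds: Sequence[int],
    shift_keys: Sequence[tuple] = ALL_SHIFT_KEYS,
    policy: Optional[PolicyConfig] = None,
    hours: float = 8.0,
) -> dict:
    """Run both policies on identical seeds/shifts and compare.

    Returns ``{"person": Metrics, "place": Metrics, "summary": dict}``
    where the summary carries paired aggregate deltas.
    """
    logs: dict[str, list] = {"person": [], "place": []}
    for key in shift_keys:
        shift = make_shift(scenario, key, behavior, hours=hours)
        for seed in seeds:
            for pol in POLICIES:
                logs[pol].append(
                    run_shift(scenario, pol, shift, behavior, seed, policy=policy)
                )
    metrics = {pol: compute_metrics(logs[pol]) for pol in POLICIES}
    summary = summarize_comparison(metrics["person"], metrics["place"])
    return {"person": metrics["person"], "place": metrics["place"], "summary": summary}


def summarize_comparison(person: Metrics, place: Metrics) -> dict:
    def med(m: Metrics) -> float:
        return float(m.arrival_delays["delay_s"].median()) if len(m.arrival_delays) else float("nan")

    def mean_std(m: Metrics) -> float:
        s = m.workload_summary()
        return float(s["std"].mean()) if len(s) else float("nan")

    return {
        "median_arrival_s": {"person": med(person), "place": med(place)},
        "workload_std": {"person": mean_std(person), "place": mean_std(place)},
        "unnecessary_arrivals_per_run": {
            "person": person.unnecessary_arrivals / person.n_runs,
            "place": place.unnecessary_arrivals / place.n_runs,
        },
        "impossible_calls_per_run": {
            "person": person.impossible_calls / person.n_runs,
            "place": place.impossible_calls / place.n_runs,
        },
        "unanswered_per_run": {
            "person": person.unanswered / person.n_runs,
            "place": place.unanswered / place.n_runs,
        },
    }
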