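"""Dispatch policies: the staged cascade, the baseline broadcast, interruptions."""

import numpy as np
import pytest

from wardcall import (
    Call,
    CallKind,
    CallStatus,
    DispatchStage,
    KnowledgeBase,
    Patient,
    PolicyConfig,
    PriorityLevel,
    Role,
    StaffMember,
    decide_interrupt,
    launch_call,
    low_priority_select,
    on_timeout,
    oncs_select,
    place_oriented_dispatch,
    rank_candidates,
    urgency_select,
)
from wardcall.errors import ConfigError, NoCandidateError, WardCallError

from conftest import make_task

POLICY = PolicyConfig()


def make_call(kb, plan, patient="p1", kind=CallKind.NORMAL, priority=PriorityLevel.NORMAL,
              maker=None, space=None):
    space = space or kb.get_patient(patient).current_location
    call = launch_call(kb, maker or patient, kind, plan.space(space), patient_id=patient)
    call.priority = priority
    return call


class TestStagedCascade:
    def test_free_responsible_nurse_wins(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1")
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.stage is DispatchStage.RESPONSIBLE
        assert decision.assignee == "n01"

    def test_responsible_busy_with_lower_priority_still_wins(self, small_kb, tiny_plan):
        small_kb.get_staff("n01").current_task = make_task(PriorityLevel.BELOW_NORMAL)
        call = make_call(small_kb, tiny_plan, "p1", priority=PriorityLevel.NORMAL)
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.stage is DispatchStage.RESPONSIBLE
        assert decision.assignee == "n01"

    def test_equal_priority_task_defers_to_free_department_nurse(self, small_kb, tiny_plan):
        small_kb.get_staff("n01").current_task = make_task(PriorityLevel.NORMAL)
        call = make_call(small_kb, tiny_plan, "p1", priority=PriorityLevel.NORMAL)
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.stage is DispatchStage.DEPARTMENT_FREE
        assert decision.assignee == "n02"

    def test_normal_call_skips_busy_lower_stage(self, small_kb, tiny_plan):
        # responsible nurse busy with an equal-priority task (stage 1 fails);
        # the other nurse busy with a lower one, but the call is not
        # Highest/High, so the busy-with-lower stages are skipped entirely
        # and the search falls through to the unconditional closest stage
        small_kb.get_staff("n01").current_task = make_task(PriorityLevel.NORMAL)
        small_kb.get_staff("n02").current_task = make_task(PriorityLevel.BELOW_NORMAL)
        call = make_call(small_kb, tiny_plan, "p1", priority=PriorityLevel.NORMAL)
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.stage is DispatchStage.CLOSEST_ANY

    def test_high_priority_call_may_take_busy_lower_nurse(self, small_kb, tiny_plan):
        for nid in ("n01", "n02"):
            small_kb.get_staff(nid).current_task = make_task(PriorityLevel.NORMAL)
        call = make_call(small_kb, tiny_plan, "p1", priority=PriorityLevel.HIGH)
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.stage in (
            DispatchStage.RESPONSIBLE,
            DispatchStage.DEPARTMENT_BUSY_LOWER,
        )
        assert decision.assignee == "n01"

    def test_head_nurse_never_selected(self, small_kb, tiny_plan):
        for nid in ("n01", "n02"):
            small_kb.get_staff(nid).current_task = make_task(PriorityLevel.HIGHEST)
        call = make_call(small_kb, tiny_plan, "p1", priority=PriorityLevel.NORMAL)
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.assignee != "head"

    def test_assistance_maker_excluded(self, small_kb, tiny_plan):
        call = make_call(
            small_kb, tiny_plan, "p1", kind=CallKind.ASSISTANCE,
            priority=PriorityLevel.HIGHEST, maker="n01",
        )
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.assignee == "n02"

    def test_no_staff_raises(self, tiny_plan):
        kb = KnowledgeBase()
        kb.add_patient(Patient(id="p1", room="room_1", current_location="room_1"))
        call = make_call(kb, tiny_plan, "p1")
        with pytest.raises(NoCandidateError):
            oncs_select(call, kb, tiny_plan, POLICY)

    def test_wrong_kind_rejected(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1", kind=CallKind.SERVICE)
        call.kind = CallKind.MEDICAL
        with pytest.raises(ConfigError):
            oncs_select(call, small_kb, tiny_plan, POLICY)

    def test_agrees_with_bruteforce_stage_evaluator(self, rng, tiny_plan):
        """Independent oracle: enumerate staff, apply stage predicates in order."""
        for trial in range(100):
            kb = KnowledgeBase()
            n_p = int(rng.integers(1, 5))
            n_s = int(rng.integers(1, 6))
            rooms = ["room_1", "room_2", "corridor_1", "nursing_post"]
            for i in range(n_p):
                kb.add_patient(
                    Patient(
                        id=f"p{i}", room="room_1", department="dept",
                        current_location=str(rng.choice(rooms)),
                    )
                )
            for j in range(n_s):
                busy = rng.random() < 0.5
                member = StaffMember(
                    id=f"n{j:02d}", role=Role.NURSE,
                    departments={"dept"} if rng.random() < 0.8 else {"other"},
                    current_location=str(rng.choice(rooms)),
                )
                if busy:
                    member.current_task = make_task(
                        PriorityLevel(int(rng.integers(1, 8)))
                    )
                if rng.random() < 0.3:
                    member.refuses_patients.add("p0")
                kb.add_staff(member)
            responsible = kb.get_staff(f"n{int(rng.integers(n_s)):02d}")
            responsible.responsible_for.add("p0")
            call = make_call(
                kb, tiny_plan, "p0",
                priority=PriorityLevel(int(rng.integers(1, 8))),
            )

            decision = oncs_select(call, kb, tiny_plan, POLICY)
            expected = brute_force_select(call, kb, tiny_plan)
            assert decision.assignee == expected, f"trial {trial}"

    def test_single_assignee_always(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1")
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        assert decision.assignee is not None and decision.broadcast_set is None


def brute_force_select(call, kb, plan):
    """Literal re-statement of the cascade used as a test oracle."""
    handlers = {Role.NURSE, Role.INTERN}
    if call.kind is CallKind.SERVICE:
        handlers.add(Role.CARETAKER)
    excluded = set(call.excluded) | {call.maker}
    patient = kb.get_patient(call.patient)
    pool = [
        s for s in kb.staff.values()
        if s.role in handlers and s.id not in excluded
    ]

    def lower(s):
        return (
            s.current_task is not None
            and call.priority is not None
            and s.current_task.priority < call.priority
        )

    def ranked(cands):
        prefs = patient.preferred_characteristics

        def key(s):
            return (
                1 if patient.id in s.refuses_patients else 0,
                -len(prefs & s.characteristics),
                plan.distance(s.current_location, patient.current_location),
                s.id,
            )

        return sorted(cands, key=key)

    resp = next((s for s in pool if patient.id in s.responsible_for), None)
    if resp is not None and (resp.current_task is None or lower(resp)):
        return resp.id
    high = call.priority in (PriorityLevel.HIGH, PriorityLevel.HIGHEST)
    for scope in (
        [s for s in pool if patient.department in s.departments],
        pool,
    ):
        free = [s for s in scope if s.current_task is None]
        if free:
            return ranked(free)[0].id
        if high:
            busy = [s for s in scope if lower(s)]
            if busy:
                return ranked(busy)[0].id
    willing_free = [
        s for s in pool
        if s.current_task is None and patient.id not in s.refuses_patients
    ]
    target = call.origin_space

    def near(cands):
        return min(
            cands, key=lambda s: (plan.distance(s.current_location, target), s.id)
        )

    if willing_free:
        return near(willing_free).id
    return near(pool).id


class TestRankCandidates:
    def test_preferred_language_first(self, small_kb, tiny_plan):
        patient = small_kb.get_patient("p1")
        patient.preferred_characteristics = {"lang:fr"}
        n01, n02 = small_kb.get_staff("n01"), small_kb.get_staff("n02")
        n01.current_location = n02.current_location = "nursing_post"
        assert rank_candidates([n02, n01], patient, tiny_plan)[0] is n01

    def test_refusing_nurse_demoted_but_listed(self, small_kb, tiny_plan):
        patient = small_kb.get_patient("p1")
        n01, n02 = small_kb.get_staff("n01"), small_kb.get_staff("n02")
        n01.refuses_patients.add("p1")
        order = rank_candidates([n01, n02], patient, tiny_plan)
        assert order[-1] is n01 and len(order) == 2

    def test_identical_candidates_ordered_by_id(self, small_kb, tiny_plan):
        patient = small_kb.get_patient("p2")
        n01, n02 = small_kb.get_staff("n01"), small_kb.get_staff("n02")
        n01.characteristics = n02.characteristics = set()
        order = rank_candidates([n02, n01], patient, tiny_plan)
        assert [s.id for s in order] == ["n01", "n02"]


class TestUrgency:
    def test_near_busy_beats_far_free(self, small_kb, tiny_plan):
        n01 = small_kb.get_staff("n01")
        n01.current_location = "room_1"
        n01.current_task = make_task(PriorityLevel.HIGH)
        n02 = small_kb.get_staff("n02")
        n02.current_location = "room_2"
        call = make_call(
            small_kb, tiny_plan, "p1", kind=CallKind.URGENCY, maker="head",
            space="room_1",
        )
        assert urgency_select(call, small_kb, tiny_plan).assignee == "n01"

    def test_single_member(self, tiny_plan):
        kb = KnowledgeBase()
        kb.add_patient(Patient(id="p1", room="room_1", current_location="room_1"))
        kb.add_staff(StaffMember(id="n01", role=Role.NURSE, current_location="room_2"))
        kb.add_staff(StaffMember(id="head", role=Role.HEAD_NURSE, current_location="room_1"))
        call = make_call(kb, tiny_plan, "p1", kind=CallKind.URGENCY, maker="head")
        assert urgency_select(call, kb, tiny_plan).assignee == "n01"

    def test_distance_optimality(self, small_kb, tiny_plan, rng):
        for _ in range(20):
            for nid in ("n01", "n02"):
                small_kb.get_staff(nid).current_location = str(
                    rng.choice(list(tiny_plan.spaces))
                )
            call = make_call(
                small_kb, tiny_plan, "p1", kind=CallKind.URGENCY, maker="head"
            )
            chosen = urgency_select(call, small_kb, tiny_plan).assignee
            d_chosen = tiny_plan.distance(
                small_kb.get_staff(chosen).current_location, call.origin_space
            )
            for other in ("n01", "n02"):
                d = tiny_plan.distance(
                    small_kb.get_staff(other).current_location, call.origin_space
                )
                assert d_chosen <= d


class TestLowPrioritySelect:
    def test_technical_call_forced_lowest_priority(self, small_kb, tiny_plan):
        small_kb.add_staff(StaffMember(id="t01", role=Role.TECHNICAL_STAFF,
                                       current_location="corridor_1"))
        call = make_call(small_kb, tiny_plan, "p1", kind=CallKind.TECHNICAL,
                         maker="n01", priority=None)
        decision = low_priority_select(call, small_kb)
        assert decision.assignee == "t01"
        assert call.priority is PriorityLevel.LOWEST

    def test_medical_prefers_free_responsible_doctor(self, small_kb, tiny_plan):
        small_kb.add_staff(StaffMember(id="d01", role=Role.DOCTOR,
                                       responsible_for=set(), current_location="corridor_1"))
        small_kb.add_staff(StaffMember(id="d02", role=Role.DOCTOR,
                                       current_location="corridor_1"))
        small_kb.get_staff("d02").responsible_for.add("p1")
        call = make_call(small_kb, tiny_plan, "p1", kind=CallKind.MEDICAL,
                         maker="n01", priority=None)
        decision = low_priority_select(call, small_kb)
        assert decision.assignee == "d02"

    def test_no_doctor_raises(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1", kind=CallKind.MEDICAL,
                         maker="n01", priority=None)
        with pytest.raises(NoCandidateError):
            low_priority_select(call, small_kb)


class TestTimeout:
    def test_new_assignee_differs_from_timed_out_one(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1")
        decision = oncs_select(call, small_kb, tiny_plan, POLICY)
        call.assignee = decision.assignee
        call.status = CallStatus.ANSWERED
        redo = on_timeout(call, small_kb, tiny_plan, POLICY, clock=180)
        assert redo.assignee != decision.assignee
        assert call.relaunch_count == 1
        assert call.status is CallStatus.ANSWERED

    def test_single_nurse_reselected_after_exclusion_reset(self, tiny_plan):
        kb = KnowledgeBase()
        kb.add_patient(Patient(id="p1", room="room_1", department="dept",
                               current_location="room_1"))
        kb.add_staff(StaffMember(id="n01", role=Role.NURSE, departments={"dept"},
                                 responsible_for={"p1"}, current_location="room_2"))
        call = make_call(kb, tiny_plan, "p1")
        call.assignee = "n01"
        call.status = CallStatus.ANSWERED
        redo = on_timeout(call, kb, tiny_plan, POLICY, clock=180)
        assert redo.assignee == "n01"

    def test_busy_call_is_left_alone(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1")
        call.status = CallStatus.BUSY
        assert on_timeout(call, small_kb, tiny_plan, POLICY, clock=180) is None


class TestPlaceOriented:
    def test_broadcast_to_all_department_nurses(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1")
        decision = place_oriented_dispatch(call, small_kb, POLICY, tiny_plan)
        assert decision.stage is DispatchStage.BROADCAST
        assert decision.broadcast_set == {"n01", "n02"}

    def test_corridor_call_is_impossible(self, small_kb, tiny_plan):
        small_kb.get_patient("p1").current_location = "corridor_1"
        call = make_call(small_kb, tiny_plan, "p1", space="corridor_1")
        decision = place_oriented_dispatch(call, small_kb, POLICY, tiny_plan)
        assert decision.stage is DispatchStage.IMPOSSIBLE
        assert call.impossible

    def test_broadcast_excludes_the_maker(self, small_kb, tiny_plan):
        call = make_call(small_kb, tiny_plan, "p1", kind=CallKind.ASSISTANCE,
                         maker="n01", priority=None)
        decision = place_oriented_dispatch(call, small_kb, POLICY, tiny_plan)
        assert decision.broadcast_set == {"n02"}

    def test_department_without_nurses_raises(self, tiny_plan):
        kb = KnowledgeBase()
        kb.add_patient(Patient(id="p1", room="room_1", department="dept",
                               current_location="room_1"))
        call = make_call(kb, tiny_plan, "p1")
        with pytest.raises(NoCandidateError):
            place_oriented_dispatch(call, kb, POLICY, tiny_plan)

    def test_urgency_has_no_timeout_entry(self):
        with pytest.raises(ConfigError):
            PolicyConfig(timeouts={CallKind.URGENCY: 60})


class TestDecideInterrupt:
    def test_equal_priority_interrupts_a_task(self, small_kb):
        nurse = small_kb.get_staff("n01")
        nurse.current_task = make_task(PriorityLevel.NORMAL)
        rng = np.random.default_rng(0)
        assert decide_interrupt(nurse, PriorityLevel.NORMAL, POLICY, rng) is True

    def test_equal_priority_does_not_interrupt_a_call(self, small_kb):
        nurse = small_kb.get_staff("n01")
        nurse.current_task = make_task(PriorityLevel.NORMAL, call_id=7)
        rng = np.random.default_rng(0)
        assert decide_interrupt(nurse, PriorityLevel.NORMAL, POLICY, rng) is False
        assert decide_interrupt(nurse, PriorityLevel.HIGH, POLICY, rng) is True

    def test_baseline_draw_is_seed_reproducible(self, small_kb):
        nurse = small_kb.get_staff("n01")
        nurse.current_task = make_task(PriorityLevel.NORMAL)
        draws1 = [
            decide_interrupt(nurse, None, POLICY, np.random.default_rng(s))
            for s in range(20)
        ]
        draws2 = [
            decide_interrupt(nurse, None, POLICY, np.random.default_rng(s))
            for s in range(20)
        ]
        assert draws1 == draws2
        assert True in draws1 and False in draws1

    def test_free_staff_has_no_decision(self, small_kb):
        nurse = small_kb.get_staff("n02")
        with pytest.raises(WardCallError):
            decide_interrupt(nurse, PriorityLevel.NORMAL, POLICY,
                             np.random.default_rng(0))
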