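import numpy as np
import pytest

from wardcall import (
    FloorPlan,
    KnowledgeBase,
    Patient,
    PriorityLevel,
    Role,
    Space,
    SpaceKind,
    StaffMember,
    Task,
    ThresholdConfig,
)
from wardcall.defaults import (
    DEFAULT_PRIORITY_ROWS,
    DEFAULT_RISK_ROWS,
    DEFAULT_THRESHOLDS,
)
from wardcall.model import TaskKind
from wardcall.priority import PriorityTable, RiskTable


@pytest.fixture(scope="session")
def risk_table():
    return RiskTable(DEFAULT_RISK_ROWS)


@pytest.fixture(scope="session")
def priority_table():
    return PriorityTable(DEFAULT_PRIORITY_ROWS)


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig(DEFAULT_THRESHOLDS)


@pytest.fixture()
def tiny_plan():
    """corridor -- room_1 (sanitary_1 attached) -- plus room_2 further away."""
    spaces = [
        Space("corridor_1", SpaceKind.CORRIDOR),
        Space("room_1", SpaceKind.PATIENT_ROOM, has_fixed_button=True),
        Space("sanitary_1", SpaceKind.SANITARY, has_fixed_button=True),
        Space("room_2", SpaceKind.PATIENT_ROOM, has_fixed_button=True),
        Space("nursing_post", SpaceKind.NURSING_POST),
    ]
    edges = [
        ("corridor_1", "room_1", 5.0),
        ("room_1", "sanitary_1", 2.0),
        ("corridor_1", "room_2", 10.0),
        ("corridor_1", "nursing_post", 4.0),
    ]
    return FloorPlan(spaces, edges)


def make_task(priority=PriorityLevel.NORMAL, call_id=None, patient=None):
    kind = TaskKind.CALL_HANDLING if call_id is not None else TaskKind.OTHER
    return Task(
        id=f"t-{priority.name.lower()}",
        kind=kind,
        priority=priority,
        patient=patient,
        call_id=call_id,
        duration=300,
        remaining=300,
    )


@pytest.fixture()
def small_kb(tiny_plan):
    """Two patients, two nurses + head nurse, responsibilities split."""
    kb = KnowledgeBase()
    kb.add_patient(
        Patient(id="p1", room="room_1", department="dept", current_location="room_1")
    )
    kb.add_patient(
        Patient(id="p2", room="room_2", department="dept", current_location="room_2")
    )
    kb.add_staff(
        StaffMember(
            id="n01", role=Role.NURSE, departments={"dept"},
            responsible_for={"p1"}, current_location="nursing_post",
            characteristics={"lang:nl", "lang:fr"},
        )
    )
    kb.add_staff(
        StaffMember(
            id="n02", role=Role.NURSE, departments={"dept"},
            responsible_for={"p2"}, current_location="nursing_post",
            characteristics={"lang:nl"},
        )
    )
    kb.add_staff(
        StaffMember(
            id="head", role=Role.HEAD_NURSE, departments={"dept"},
            current_location="nursing_post",
        )
    )
    return kb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
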