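"""Synthetic scenario generation.

Emulates the studied ward: 26 beds at 84.62% occupancy (22 patients),
risk factors drawn from the reference count distribution and weights with
co-occurrence boosts, a shift roster of 5/4/2 nurses (week) and 4/3/2
(weekend) plus a head nurse who never answers calls, staff language
profiles, and contiguous room-block responsibility assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import defaults
from .errors import ConfigError
from .floorplan import FloorPlan, build_default_plan
from .model import Patient, RiskFactor, Role, StaffMember, CallKind
from .priority import (
    PriorityTable,
    RiskTable,
    ThresholdConfig,
    assign_risk_groups,
    priority_bounds,
)


@dataclass
class ScenarioConfig:
    bed_count: int = 26
    occupancy: float = 0.8462
    beds_per_room: int = 2
    risk_count_distribution: Sequence[float] = defaults.DEFAULT_RISK_COUNT_DISTRIBUTION
    factor_weights: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_FACTOR_WEIGHTS)
    )
    cooccurrence_pairs: Sequence = defaults.DEFAULT_COOCCURRENCE_PAIRS
    cooccurrence_boost: float = 3.0
    max_factors: int = 3  # realization of "> 2 risk factors"
    staff_languages: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_STAFF_LANGUAGES)
    )
    patient_only_languages: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_PATIENT_ONLY_LANGUAGES)
    )
    shift_roster: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_SHIFT_ROSTER)
    )
    department: str = "dept"
    calibration_kind_mix: dict = field(
        default_factory=lambda: dict(defaults.DEFAULT_CALIBRATION_KIND_MIX)
    )

    def __post_init__(self):
        if not (0.0 < self.occupancy <= 1.0):
            raise ConfigError("occupancy must lie in (0, 1]")
        rcd = tuple(float(x) for x in self.risk_count_distribution)
        if len(rcd) != 4 or abs(sum(rcd) - 1.0) > 1e-9:
            raise ConfigError("risk_count_distribution must be 4 proportions summing to 1")
        if any(w < 0 for w in self.factor_weights.values()):
            raise ConfigError("factor weights must be non-negative")
        self.risk_count_distribution = rcd

    @property
    def patient_count(self) -> int:
        return int(round(self.bed_count * self.occupancy))


@dataclass
class Scenario:
    """A concrete, reproducible ward instance plus its probability tables."""

    config: ScenarioConfig
    plan: FloorPlan
    risk_table: RiskTable
    priority_table: PriorityTable
    thresholds: ThresholdConfig
    patients: list = field(default_factory=list)


def default_scenario_config() -> ScenarioConfig:
    return ScenarioConfig()


def build_scenario(
    config: Optional[ScenarioConfig] = None,
    seed: int = 0,
    plan: Optional[FloorPlan] = None,
    risk_table: Optional[RiskTable] = None,
    priority_table: Optional[PriorityTable] = None,
    thresholds: Optional[ThresholdConfig] = None,
) -> Scenario:
    """Materialize a scenario instance: floor plan, tables, patients."""
    config = config or ScenarioConfig()
    plan = plan or build_default_plan(department=config.department)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC3]))
    patients = generate_patients(config, rng, plan=plan)
    return Scenario(
        config=config,
        plan=plan,
        risk_table=risk_table or _lazy_default_risk(),
        priority_table=priority_table or _lazy_default_priority(),
        thresholds=thresholds or ThresholdConfig(defaults.DEFAULT_THRESHOLDS),
        patients=patients,
    )


def _lazy_default_risk() -> RiskTable:
    return RiskTable(defaults.DEFAULT_RISK_ROWS)


def _lazy_default_priority() -> PriorityTable:
    return PriorityTable(defaults.DEFAULT_PRIORITY_ROWS)


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------


def sample_risk_factors(cfg: ScenarioConfig, rng) -> set:
    """Draw a patient's risk-factor set.

    The number of factors follows the count distribution (>2 realized as
    ``cfg.max_factors``); factors are drawn without replacement with
    probability proportional to their weights, and once a factor is drawn
    the weights of its listed co-occurrence partners are multiplied by the
    boost. Zero-weight factors are never drawn.
    """
    n_choices = rng.choice(
        [0, 1, 2, cfg.max_factors], p=np.asarray(cfg.risk_count_distribution)
    )
    weights = {RiskFactor(f): float(w) for f, w in cfg.factor_weights.items()}
    partners: dict[RiskFactor, list] = {}
    for a, b in cfg.cooccurrence_pairs:
        partners.setdefault(RiskFactor(a), []).append(RiskFactor(b))
        partners.setdefault(RiskFactor(b), []).append(RiskFactor(a))
    drawn: set = set()
    for _ in range(int(n_choices)):
        pool = [(f, w) for f, w in weights.items() if f not in drawn and w > 0]
        if not pool:
            break
        factors, w = zip(*pool)
        p = np.asarray(w, dtype=float)
        pick = factors[rng.choice(len(factors), p=p / p.sum())]
        drawn.add(pick)
        for partner in partners.get(pick, []):
            if weights.get(partner, 0) > 0:
                weights[partner] *= cfg.cooccurrence_boost
    return drawn


def generate_patients(
    cfg: ScenarioConfig, rng, plan: Optional[FloorPlan] = None
) -> list[Patient]:
    """Generate the ward census: ``round(bed_count * occupancy)`` patients.

    Beds are filled room by room along the corridor; the unoccupied beds
    are chosen at random. Patients start in their own room.
    """
    n_patients = cfg.patient_count
    if n_patients < 1:
        raise ConfigError("census is empty; raise bed_count or occupancy")
    n_rooms = -(-cfg.bed_count // cfg.beds_per_room)  # ceil
    beds = [
        (f"room_{r}", f"room_{r}_bed_{b}")
        for r in range(1, n_rooms + 1)
        for b in range(1, cfg.beds_per_room + 1)
    ][: cfg.bed_count]
    occupied_idx = sorted(rng.choice(len(beds), size=n_patients, replace=False))
    patients = []
    for i, bed_idx in enumerate(occupied_idx, start=1):
        room, bed = beds[bed_idx]
        factors = sample_risk_factors(cfg, rng)
        preferred = set()
        characteristics = set()
        u = rng.random()
        acc = 0.0
        for lang, frac in cfg.patient_only_languages.items():
            acc += frac
            if u < acc:
                preferred.add(f"lang:{lang}")
                characteristics.add(f"lang:{lang}")
                break
        else:
            characteristics.add("lang:nl")
        patients.append(
            Patient(
                id=f"p{i:02d}",
                bed=bed,
                room=room,
                department=cfg.department,
                risk_factors=factors,
                preferred_characteristics=preferred,
                current_location=room,
                mobile=True,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Staff
# ---------------------------------------------------------------------------


def generate_staff(cfg: ScenarioConfig, shift: tuple, rng) -> list[StaffMember]:
    """Generate the nurses of a shift plus the head nurse.

    ``shift`` is a ``(week_part, shift_name)`` key into the roster, e.g.
    ``("week", "early")``. Everyone speaks Dutch; other languages are
    sampled per the staff language profile. The head nurse is registered
    but never receives calls (the dispatch layer never selects that role).
    """
    try:
        nurse_count = int(cfg.shift_roster[tuple(shift)])
    except KeyError:
        raise ConfigError(f"unknown shift {shift!r}") from None
    if nurse_count < 1:
        raise ConfigError(f"shift {shift!r} has no nurses rostered")
    members = []
    for i in range(1, nurse_count + 1):
        characteristics = set()
        for lang, frac in cfg.staff_languages.items():
            if frac >= 1.0 or rng.random() < frac:
                if frac > 0.0:
                    characteristics.add(f"lang:{lang}")
        members.append(
            StaffMember(
                id=f"n{i:02d}",
                role=Role.NURSE,
                departments={cfg.department},
                characteristics=characteristics,
                current_location="nursing_post",
            )
        )
    members.append(
        StaffMember(
            id="head",
            role=Role.HEAD_NURSE,
            departments={cfg.department},
            characteristics={"lang:nl"},
            current_location="office",
        )
    )
    return members


def assign_responsibilities(patients: Sequence[Patient], nurses) -> dict:
    """Split the rooms into contiguous blocks, one block per nurse.

    Rooms are ordered along the corridor; block sizes differ by at most
    one patient, and every patient is covered exactly once. Updates each
    nurse's ``responsible_for`` set and returns nurse id -> set of patient
    ids.
    """
    nurses = [n for n in nurses if n.role is Role.NURSE]
    if not nurses:
        raise ConfigError("need at least one nurse")
    ordered = sorted(patients, key=lambda p: (_room_index(p.room), p.bed))
    n = len(ordered)
    k = len(nurses)
    base, extra = divmod(n, k)
    blocks: dict[str, set] = {}
    start = 0
    for i, nurse in enumerate(sorted(nurses, key=lambda x: x.id)):
        size = base + (1 if i < extra else 0)
        block = {p.id for p in ordered[start : start + size]}
        nurse.responsible_for = set(block)
        blocks[nurse.id] = block
        start += size
    return blocks


def _room_index(room: str) -> int:
    try:
        return int(room.rsplit("_", 1)[-1])
    except ValueError:
        return 0


# ---------------------------------------------------------------------------
# Calibration calls
# ---------------------------------------------------------------------------


def generate_calibration_calls(
    cfg: ScenarioConfig,
    n: int,
    rng,
    risk_table: Optional[RiskTable] = None,
    priority_table: Optional[PriorityTable] = None,
) -> list:
    """Generate ``n`` synthetic calls as priority-bound 7-vectors.

    Each call draws a synthetic patient risk profile per the census
    configuration and a call kind from the patient-call mix, then maps it
    through the priority engine.
    """
    if n <= 0:
        raise ConfigError("need n > 0 calibration calls")
    risk_table = risk_table or _lazy_default_risk()
    priority_table = priority_table or _lazy_default_priority()
    kinds = list(cfg.calibration_kind_mix)
    probs = np.asarray([cfg.calibration_kind_mix[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    vectors = []
    for _ in range(n):
        factors = sample_risk_factors(cfg, rng)
        assignment = assign_risk_groups(factors, risk_table)
        kind = kinds[rng.choice(len(kinds), p=probs)]
        vectors.append(priority_bounds(assignment, CallKind(kind), priority_table))
    return vectors
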