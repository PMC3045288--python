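"""Default probability tables, thresholds and behavior parameters.

Two rows of the risk table (diabetes, heart disease) and the normal-call
priority rows are the reference values; every other entry is a
repo-authored synthetic default, shaped to plausible clinical intuition
(e.g. sanitary-assistance calls concentrate on the Highest/High levels)
and fully overridable through the JSON config interface.
"""

from __future__ import annotations

from .model import CallKind, RiskFactor
from .priority import PriorityTable, RiskTable, ThresholdConfig

# ---------------------------------------------------------------------------
# Risk table: factor -> (high, medium, low) probability intervals
# ---------------------------------------------------------------------------

#: Reference rows: diabetes and heart disease. The remaining 13 factors are
#: synthetic defaults following the same shape ([l,1], [0,u], [0,u]), which
#: guarantees consistent (non-empty) intersections for any factor combination.
DEFAULT_RISK_ROWS = {
    RiskFactor.DIABETES: ((0.5, 1.0), (0.0, 0.3), (0.0, 0.2)),
    RiskFactor.HEART_DISEASE: ((0.5, 1.0), (0.0, 0.4), (0.0, 0.1)),
    # synthetic rows below
    RiskFactor.HIGH_AGE: ((0.3, 1.0), (0.0, 0.5), (0.0, 0.4)),
    RiskFactor.HIGH_FALL_RISK: ((0.4, 1.0), (0.0, 0.4), (0.0, 0.3)),
    RiskFactor.NEUROLOGIC_PROBLEM: ((0.4, 1.0), (0.0, 0.4), (0.0, 0.2)),
    RiskFactor.TRACHEOTOMY: ((0.6, 1.0), (0.0, 0.3), (0.0, 0.1)),
    RiskFactor.COPD: ((0.5, 1.0), (0.0, 0.4), (0.0, 0.2)),
    RiskFactor.PARAPLEGIA: ((0.3, 1.0), (0.0, 0.5), (0.0, 0.3)),
    RiskFactor.PNEUMONIA: ((0.4, 1.0), (0.0, 0.4), (0.0, 0.2)),
    RiskFactor.DISORIENTED_CONFUSED: ((0.3, 1.0), (0.0, 0.6), (0.0, 0.4)),
    RiskFactor.GASTRIC_BLEEDING_48H: ((0.6, 1.0), (0.0, 0.3), (0.0, 0.1)),
    RiskFactor.TRANSFERRED_FROM_ICU: ((0.5, 1.0), (0.0, 0.4), (0.0, 0.2)),
    RiskFactor.TRANSFERRED_FROM_ICU_72H: ((0.7, 1.0), (0.0, 0.2), (0.0, 0.1)),
    RiskFactor.REANIMATED: ((0.6, 1.0), (0.0, 0.3), (0.0, 0.1)),
    RiskFactor.REANIMATED_72H: ((0.8, 1.0), (0.0, 0.2), (0.0, 0.05)),
}


def default_risk_table() -> RiskTable:
    return RiskTable(DEFAULT_RISK_ROWS)


# ---------------------------------------------------------------------------
# Priority table: (call kind, risk group) -> 7 probabilities Highest->Lowest
# ---------------------------------------------------------------------------

#: Normal-call rows are the reference distribution; the rows for
#: the other patient/assistance call kinds are synthetic defaults.
DEFAULT_PRIORITY_ROWS = {
    (CallKind.NORMAL, "high"): (0.0, 0.2, 0.6, 0.2, 0.0, 0.0, 0.0),
    (CallKind.NORMAL, "medium"): (0.0, 0.0, 0.3, 0.6, 0.1, 0.0, 0.0),
    (CallKind.NORMAL, "low"): (0.0, 0.0, 0.0, 0.6, 0.3, 0.1, 0.0),
    # synthetic rows below; shaped so that under the default thresholds
    # assistance-type calls land on Highest/High, sanitary calls sit a notch
    # above normal calls, and service calls stay in the middle band
    (CallKind.SANITARY, "high"): (0.0, 0.2, 0.5, 0.3, 0.0, 0.0, 0.0),
    (CallKind.SANITARY, "medium"): (0.0, 0.1, 0.4, 0.4, 0.1, 0.0, 0.0),
    (CallKind.SANITARY, "low"): (0.0, 0.1, 0.3, 0.4, 0.2, 0.0, 0.0),
    (CallKind.SERVICE, "high"): (0.0, 0.1, 0.3, 0.4, 0.2, 0.0, 0.0),
    (CallKind.SERVICE, "medium"): (0.0, 0.0, 0.2, 0.5, 0.3, 0.0, 0.0),
    (CallKind.SERVICE, "low"): (0.0, 0.0, 0.1, 0.5, 0.3, 0.1, 0.0),
    (CallKind.ASSISTANCE, "high"): (0.7, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0),
    (CallKind.ASSISTANCE, "medium"): (0.4, 0.4, 0.2, 0.0, 0.0, 0.0, 0.0),
    (CallKind.ASSISTANCE, "low"): (0.15, 0.55, 0.2, 0.1, 0.0, 0.0, 0.0),
    (CallKind.SANITARY_ASSISTANCE, "high"): (0.8, 0.15, 0.05, 0.0, 0.0, 0.0, 0.0),
    (CallKind.SANITARY_ASSISTANCE, "medium"): (0.7, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0),
    (CallKind.SANITARY_ASSISTANCE, "low"): (0.7, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0),
}


def default_priority_table() -> PriorityTable:
    return PriorityTable(DEFAULT_PRIORITY_ROWS)


# ---------------------------------------------------------------------------
# Thresholds and calibration target
# ---------------------------------------------------------------------------

#: Reference department thresholds, ordered Highest -> Lowest.
DEFAULT_THRESHOLDS = (0.21, 0.30, 0.24, 0.0, 0.05, 0.0, 0.0)

#: Target share of calls per priority used for threshold calibration.
DEFAULT_TARGET_DISTRIBUTION = (0.05, 0.10, 0.25, 0.35, 0.25, 0.0, 0.0)


def default_thresholds() -> ThresholdConfig:
    return ThresholdConfig(DEFAULT_THRESHOLDS)


# ---------------------------------------------------------------------------
# Census and staffing
# ---------------------------------------------------------------------------

#: Counts of patients with 0 / 1 / 2 / >2 risk factors (out of 30), used as
#: sampling proportions.
DEFAULT_RISK_COUNT_DISTRIBUTION = (10 / 30, 10 / 30, 8 / 30, 2 / 30)

#: Relative risk-factor weights in percent.
DEFAULT_FACTOR_WEIGHTS = {
    RiskFactor.HIGH_AGE: 50,
    RiskFactor.DIABETES: 10,
    RiskFactor.HEART_DISEASE: 3,
    RiskFactor.HIGH_FALL_RISK: 5,
    RiskFactor.NEUROLOGIC_PROBLEM: 3,
    RiskFactor.TRACHEOTOMY: 10,
    RiskFactor.COPD: 3,
    RiskFactor.PARAPLEGIA: 3,
    RiskFactor.PNEUMONIA: 3,
    RiskFactor.DISORIENTED_CONFUSED: 5,
    RiskFactor.GASTRIC_BLEEDING_48H: 3,
    RiskFactor.TRANSFERRED_FROM_ICU: 1,
    RiskFactor.TRANSFERRED_FROM_ICU_72H: 0,
    RiskFactor.REANIMATED: 1,
    RiskFactor.REANIMATED_72H: 0,
}

#: Risk-factor pairs that co-occur more often than independence suggests;
#: once the first member is drawn, the partner's weight is boosted.
DEFAULT_COOCCURRENCE_PAIRS = (
    (RiskFactor.COPD, RiskFactor.TRACHEOTOMY),
    (RiskFactor.HIGH_AGE, RiskFactor.DISORIENTED_CONFUSED),
    (RiskFactor.HIGH_AGE, RiskFactor.HIGH_FALL_RISK),
    (RiskFactor.DIABETES, RiskFactor.DISORIENTED_CONFUSED),
    (RiskFactor.NEUROLOGIC_PROBLEM, RiskFactor.DISORIENTED_CONFUSED),
    (RiskFactor.TRANSFERRED_FROM_ICU, RiskFactor.TRACHEOTOMY),
)

#: Fraction of staff speaking each language (everyone speaks Dutch).
DEFAULT_STAFF_LANGUAGES = {"nl": 1.0, "en": 0.8, "fr": 0.7, "de": 0.2, "it": 0.0, "es": 0.0}

#: Fraction of patients speaking only the given language.
DEFAULT_PATIENT_ONLY_LANGUAGES = {"fr": 0.02, "de": 0.03}

#: Nurses per shift: (week/weekend, shift name) -> count. Night staffing of
#: "1 or 2" is resolved to 2 by default.
DEFAULT_SHIFT_ROSTER = {
    ("week", "early"): 5,
    ("week", "late"): 4,
    ("week", "night"): 2,
    ("weekend", "early"): 4,
    ("weekend", "late"): 3,
    ("weekend", "night"): 2,
}

# ---------------------------------------------------------------------------
# Behavior defaults (simulator)
# ---------------------------------------------------------------------------

#: Per-patient per-tick probability of launching a call.
DEFAULT_CALL_RATE = 0.001164021

#: Per-tick probability that a nurse handling a call launches an
#: (sanitary) assistance call.
DEFAULT_ASSISTANCE_RATE = 0.0007386

#: Synthetic nurse background-task mix: category -> (time share,
#: mean duration s, priority). Interruptibility follows from the priority.
DEFAULT_TASK_MIX = {
    "medication_round": (0.25, 600, "NORMAL"),
    "hygiene_care": (0.25, 480, "BELOW_NORMAL"),
    "administration": (0.20, 420, "LOW"),
    "patient_transfer": (0.10, 360, "ABOVE_NORMAL"),
    "break": (0.20, 300, "LOWEST"),
}

#: Synthetic call-reason mix: reason -> (probability, mean service duration
#: s, requested call kind). The kind may still be transformed by the space
#: the call is made in (normal -> sanitary inside a sanitary space).
DEFAULT_CALL_REASON_MIX = {
    "toileting": (0.25, 300, "normal"),
    "pain_medication": (0.20, 180, "normal"),
    "iv_pump_alarm": (0.15, 120, "normal"),
    "position_change": (0.15, 200, "normal"),
    "beverage_request": (0.15, 120, "service"),
    "accidental": (0.10, 30, "normal"),
}

#: Synthetic share of time patients spend per space category.
DEFAULT_PATIENT_SPACE_BUDGET = {
    "own_room": 0.80,
    "sanitary": 0.08,
    "corridor": 0.03,
    "smoking_area": 0.04,
    "cafeteria": 0.03,
    "ct_scanner": 0.02,
}

#: Mean dwell seconds per space category once there.
DEFAULT_DWELL_MEANS = {
    "own_room": 1800,
    "sanitary": 300,
    "corridor": 120,
    "smoking_area": 600,
    "cafeteria": 900,
    "ct_scanner": 900,
}

#: Mix of patient-call kinds used when generating calibration calls.
DEFAULT_CALIBRATION_KIND_MIX = {
    CallKind.NORMAL: 0.55,
    CallKind.SANITARY: 0.25,
    CallKind.SERVICE: 0.12,
    CallKind.ASSISTANCE: 0.05,
    CallKind.SANITARY_ASSISTANCE: 0.03,
}
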