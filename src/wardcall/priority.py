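"""Probabilistic priority assessment.

Risk-factor knowledge is expressed as probability intervals: each factor
maps to intervals bounding the chance that a patient carrying it belongs to
the High, Medium and Low risk group. A patient's group membership is the
intersection of the intervals of all their factors. A conditional table
gives, per call kind and risk group, the probability that a call gets each
of the seven priority levels; linear interval propagation turns the group
intervals into a 7-vector of priority probability intervals. A threshold
walk over the lower bounds (Highest first, first level whose lower bound
meets its threshold wins) picks the single assigned priority.

The threshold vector itself is calibrated against a target priority
distribution by exact grid search over a reduced candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, InconsistentIntervalsError
from .model import (
    PRIORITY_DESC,
    CallKind,
    Patient,
    PriorityLevel,
    ProbabilityInterval,
    RiskFactor,
)

RISK_GROUPS = ("high", "medium", "low")


# ---------------------------------------------------------------------------
# Tables and configs
# ---------------------------------------------------------------------------


@dataclass
class RiskTable:
    """Per risk factor: (high, medium, low) probability-interval triple."""

    rows: Mapping[RiskFactor, tuple]

    def __post_init__(self):
        rows = {}
        for factor, triple in dict(self.rows).items():
            factor = RiskFactor(factor)
            triple = tuple(
                iv if isinstance(iv, ProbabilityInterval) else ProbabilityInterval(*iv)
                for iv in triple
            )
            if len(triple) != 3:
                raise ConfigError(f"risk row for {factor} needs 3 intervals")
            rows[factor] = triple
        missing = set(RiskFactor) - set(rows)
        if missing:
            raise ConfigError(
                "risk table missing factors: "
                + ", ".join(sorted(f.value for f in missing))
            )
        self.rows = rows

    def __getitem__(self, factor: RiskFactor) -> tuple:
        return self.rows[RiskFactor(factor)]


@dataclass
class PriorityTable:
    """Conditional priority distribution per (call kind, risk group).

    Each row is a 7-vector of probabilities ordered Highest -> Lowest and
    sums to 1; absent table cells are zeros.
    """

    rows: Mapping

    def __post_init__(self):
        rows = {}
        for key, vec in dict(self.rows).items():
            kind, group = key
            kind = CallKind(kind)
            if group not in RISK_GROUPS:
                raise ConfigError(f"unknown risk group {group!r}")
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (7,):
                raise ConfigError(f"priority row {key} must have 7 entries")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"priority row {kind.value}/{group} sums to {vec.sum():.6f}, not 1"
                )
            rows[(kind, group)] = vec
        self.rows = rows

    def row(self, kind: CallKind, group: str) -> np.ndarray:
        try:
            return self.rows[(CallKind(kind), group)]
        except KeyError:
            raise ConfigError(
                f"no priority row for call kind {CallKind(kind).value!r}, "
                f"risk group {group!r}"
            ) from None


@dataclass
class ThresholdConfig:
    """Seven thresholds ordered Highest -> Lowest; at least one must be 0
    so the threshold walk always terminates."""

    thresholds: Sequence[float]

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 7:
            raise ConfigError("need exactly 7 thresholds")
        if any(not (0.0 <= x <= 1.0) for x in t):
            raise ConfigError("thresholds must lie in [0, 1]")
        if min(t) > 0.0:
            raise ConfigError("at least one threshold must be 0")
        self.thresholds = t

    def __iter__(self):
        return iter(self.thresholds)

    def __getitem__(self, i):
        return self.thresholds[i]


@dataclass
class CalibrationConfig:
    """Target priority distribution and search grid for threshold calibration."""

    target_distribution: Sequence[float] = (0.05, 0.10, 0.25, 0.35, 0.25, 0.0, 0.0)
    grid_step: float = 0.01
    call_sample_size: int = 22500

    def __post_init__(self):
        t = tuple(float(x) for x in self.target_distribution)
        if len(t) != 7 or abs(sum(t) - 1.0) > 1e-9:
            raise ConfigError("target distribution must be 7 proportions summing to 1")
        n_steps = 1.0 / self.grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("grid_step must divide 1")
        self.target_distribution = t


@dataclass(frozen=True)
class RiskGroupAssignment:
    """Probability intervals of a patient belonging to each risk group."""

    high: ProbabilityInterval
    medium: ProbabilityInterval
    low: ProbabilityInterval

    def as_dict(self):
        return {"high": self.high, "medium": self.medium, "low": self.low}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def intersect_intervals(
    intervals: Iterable[ProbabilityInterval],
    sources: Optional[Sequence] = None,
) -> ProbabilityInterval:
    """Intersection of probability intervals: [max of lowers, min of uppers].

    Raises :class:`InconsistentIntervalsError` when the intersection is
    empty, naming the offending sources when given.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("cannot intersect an empty list of intervals")
    lower = max(iv.lower for iv in intervals)
    upper = min(iv.upper for iv in intervals)
    if lower > upper + 1e-12:
        names = tuple(sources) if sources is not None else ()
        raise InconsistentIntervalsError(
            f"empty intersection: max lower {lower} > min upper {upper}"
            + (f" (sources: {', '.join(map(str, names))})" if names else ""),
            sources=names,
        )
    return ProbabilityInterval(lower, min(upper, 1.0))


def assign_risk_groups(patient, table: RiskTable) -> RiskGroupAssignment:
    """Combine a patient's risk factors into risk-group intervals.

    For each group the per-factor intervals are intersected. A patient
    without any risk factor is certainly low risk:
    high = medium = [0, 0], low = [1, 1].
    """
    factors = patient.risk_factors if isinstance(patient, Patient) else patient
    factors = sorted(RiskFactor(f) for f in factors)
    if not factors:
        zero, one = ProbabilityInterval.point(0.0), ProbabilityInterval.point(1.0)
        return RiskGroupAssignment(high=zero, medium=zero, low=one)
    combined = []
    for gi in range(3):
        combined.append(
            intersect_intervals(
                [table[f][gi] for f in factors],
                sources=[f.value for f in factors],
            )
        )
    return RiskGroupAssignment(*combined)


def priority_bounds(
    assignment: RiskGroupAssignment, kind: CallKind, table: PriorityTable
) -> tuple:
    """Propagate risk-group intervals to per-priority probability intervals.

    For priority level k (ordered Highest -> Lowest):
    ``lower_k = sum_r c[r,k] * lower(group r)`` and
    ``upper_k = min(1, sum_r c[r,k] * upper(group r))``, with blank table
    cells contributing zero.
    """
    groups = assignment.as_dict()
    lowers = np.zeros(7)
    uppers = np.zeros(7)
    for group in RISK_GROUPS:
        c = table.row(kind, group)
        lowers += c * groups[group].lower
        uppers += c * groups[group].upper
    uppers = np.minimum(uppers, 1.0)
    # guard against float fuzz producing lower > upper on point intervals
    uppers = np.maximum(uppers, lowers)
    return tuple(
        ProbabilityInterval(float(lo), float(up)) for lo, up in zip(lowers, uppers)
    )


def assign_priority(bounds: Sequence, theta: ThresholdConfig) -> PriorityLevel:
    """Threshold walk over interval lower bounds, Highest -> Lowest.

    Returns the first level whose lower bound is >= its threshold; some
    threshold is 0, so the walk always returns.
    """
    if not isinstance(theta, ThresholdConfig):
        theta = ThresholdConfig(theta)
    lowers = _lower_vector(bounds)
    for level, lo, th in zip(PRIORITY_DESC, lowers, theta):
        if lo >= th - 1e-12:
            return level
    raise AssertionError("unreachable: some threshold is 0")


def _lower_vector(bounds) -> np.ndarray:
    return np.asarray(
        [b.lower if isinstance(b, ProbabilityInterval) else float(b[0]) for b in bounds],
        dtype=float,
    )


def achieved_distribution(
    samples: Sequence, theta: ThresholdConfig
) -> np.ndarray:
    """Proportion of sample calls assigned to each level (Highest -> Lowest)."""
    counts = np.zeros(7)
    index = {level: i for i, level in enumerate(PRIORITY_DESC)}
    for bounds in samples:
        counts[index[assign_priority(bounds, theta)]] += 1
    return counts / max(len(samples), 1)


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------


def calibrate_thresholds(
    bound_samples: Sequence, cfg: CalibrationConfig
) -> ThresholdConfig:
    """Exact grid search for the thresholds best matching a target distribution.

    Minimizes the L1 distance between the achieved priority proportions of
    the sample under the threshold walk and ``cfg.target_distribution``,
    over the grid with step ``cfg.grid_step`` per component; ties are broken
    by the lexicographically smallest threshold vector.

    Rather than enumerating the full grid, per level only the smallest grid
    value realizing each distinct capture set of the sample is considered
    (any other grid value assigns the identical priorities, with a
    lexicographically larger vector), which makes the search exact and
    tractable. Depth-first enumeration prunes on the accumulated L1 and
    collapses to all-zero suffixes once every sample is captured.
    """
    if len(bound_samples) == 0:
        raise ValueError("cannot calibrate on an empty sample")

    # weighted unique lower-bound vectors
    lowers = np.asarray([_lower_vector(b) for b in bound_samples], dtype=float)
    lowers = np.round(lowers, 12)
    unique, counts = np.unique(lowers, axis=0, return_counts=True)
    n_total = counts.sum()
    target = np.asarray(cfg.target_distribution, dtype=float)
    step = cfg.grid_step
    n_grid = int(round(1.0 / step))

    def grid_candidates(values: np.ndarray) -> list[float]:
        """Smallest grid value per distinct capture set of coordinate values.

        The capture set {x : x >= theta} is constant for theta in
        (v_{i-1}, v_i]; the smallest grid multiple in that interval is the
        lexicographically preferred representative. theta = 0 covers the
        capture-everything class; one extra value covers capture-nothing.
        """
        vals = np.unique(values)
        cands = [0.0]
        for prev, v in zip(vals[:-1], vals[1:]):
            m = int(np.floor(prev / step + 1e-9)) + 1  # smallest grid > prev
            if m * step <= v + 1e-12 and m <= n_grid:
                cands.append(round(m * step, 12))
        m_empty = int(np.floor(vals[-1] / step + 1e-9)) + 1
        if m_empty <= n_grid:
            cands.append(round(m_empty * step, 12))
        return sorted(set(cands))

    candidates = [grid_candidates(unique[:, k]) for k in range(7)]

    best: dict = {"l1": np.inf, "theta": None}

    def dfs(level: int, alive: np.ndarray, acc_l1: float, prefix: tuple):
        if acc_l1 > best["l1"] + 1e-12:
            return
        if not alive.any():
            # remaining levels capture nothing; zero-fill is lexicographically
            # smallest and keeps the termination invariant
            l1 = acc_l1 + float(target[level:].sum())
            theta = prefix + (0.0,) * (7 - level)
            _consider(l1, theta)
            return
        if level == 6:
            # last level must capture all survivors: threshold 0
            p = counts[alive].sum() / n_total
            l1 = acc_l1 + abs(p - target[6])
            _consider(l1, prefix + (0.0,))
            return
        for th in candidates[level]:
            captured = alive & (unique[:, level] >= th - 1e-12)
            p = counts[captured].sum() / n_total
            new_l1 = acc_l1 + abs(p - target[level])
            if new_l1 > best["l1"] + 1e-12:
                continue
            dfs(level + 1, alive & ~captured, new_l1, prefix + (th,))

    def _consider(l1: float, theta: tuple):
        if l1 < best["l1"] - 1e-12 or (
            abs(l1 - best["l1"]) <= 1e-12
            and (best["theta"] is None or theta < best["theta"])
        ):
            best["l1"] = l1
            best["theta"] = theta

    dfs(0, np.ones(len(unique), dtype=bool), 0.0, ())
    return ThresholdConfig(best["theta"])
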