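"""Ward floor plan as a weighted graph, travel distances and movement.

Geometry is abstracted to a connected undirected graph whose edge weights
are walking distances in meters; at the default walking speed of 1 m/s the
weights double as travel times in seconds. Agents occupy either a space or
a point part-way along a shortest path (a :class:`Position`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .errors import ConfigError, UnknownEntityError


class SpaceKind(str, Enum):
    PATIENT_ROOM = "patient_room"
    SANITARY = "sanitary"
    CORRIDOR = "corridor"
    NURSING_POST = "nursing_post"
    OFFICE = "office"
    STORAGE = "storage"
    REMOTE = "remote"


@dataclass(frozen=True)
class Space:
    id: str
    kind: SpaceKind
    has_fixed_button: bool = False
    department: Optional[str] = None

    def __post_init__(self):
        kind = SpaceKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.has_fixed_button and kind not in (
            SpaceKind.PATIENT_ROOM,
            SpaceKind.SANITARY,
        ):
            raise ConfigError(
                f"space {self.id!r}: fixed call buttons only exist in patient "
                "rooms and sanitary spaces"
            )


class FloorPlan:
    """Connected weighted graph of ward spaces with cached shortest paths."""

    def __init__(self, spaces: Iterable[Space], edges: Iterable[tuple]):
        self.spaces: dict[str, Space] = {s.id: s for s in spaces}
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.spaces)
        for a, b, length in edges:
            if a not in self.spaces or b not in self.spaces:
                raise ConfigError(f"edge ({a}, {b}) references unknown space")
            if length <= 0:
                raise ConfigError(f"edge ({a}, {b}) must have positive length")
            if self.graph.has_edge(a, b):
                length = min(length, self.graph.edges[a, b]["weight"])
            self.graph.add_edge(a, b, weight=float(length))
        if len(self.spaces) > 1 and not nx.is_connected(self.graph):
            raise ConfigError("floor plan graph must be connected")
        self._dist = dict(nx.all_pairs_dijkstra_path_length(self.graph))
        self._route_cache: dict[tuple, list] = {}

    def space(self, space_id: str) -> Space:
        try:
            return self.spaces[space_id]
        except KeyError:
            raise UnknownEntityError(f"unknown space {space_id!r}") from None

    def distance(self, a: str, b: str) -> float:
        """Shortest-path walking distance in meters; distance(a, a) == 0."""
        self.space(a), self.space(b)
        return self._dist[a][b]

    def route(self, a: str, b: str) -> list:
        key = (a, b)
        if key not in self._route_cache:
            self._route_cache[key] = nx.dijkstra_path(self.graph, a, b)
        return self._route_cache[key]

    def edge_length(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def to_json(self) -> dict:
        return {
            "spaces": [
                {
                    "id": s.id,
                    "kind": s.kind.value,
                    "has_fixed_button": s.has_fixed_button,
                    "department": s.department,
                }
                for s in self.spaces.values()
            ],
            "edges": [
                [a, b, d["weight"]] for a, b, d in self.graph.edges(data=True)
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "FloorPlan":
        spaces = [
            Space(
                id=s["id"],
                kind=SpaceKind(s["kind"]),
                has_fixed_button=bool(s.get("has_fixed_button", False)),
                department=s.get("department"),
            )
            for s in data["spaces"]
        ]
        return cls(spaces, [tuple(e) for e in data["edges"]])


def nearest(plan: FloorPlan, candidates, target: str):
    """Candidate staff member closest to ``target``; ties by smallest id.

    Candidates are objects with ``id`` and ``current_location`` attributes.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("nearest() needs a non-empty candidate set")
    return min(
        candidates, key=lambda s: (plan.distance(s.current_location, target), s.id)
    )


@dataclass
class Position:
    """Location of an agent: a space, optionally en route toward a target.

    ``remaining`` is the walking distance left to ``target`` along the
    shortest path computed when the walk began. ``space`` tracks the last
    node reached and is what distance queries against other spaces use.
    """

    space: str
    target: Optional[str] = None
    path: list = field(default_factory=list)  # nodes still ahead (ends at target)
    into_edge: float = 0.0  # meters progressed toward path[0]
    remaining: float = 0.0

    @property
    def arrived(self) -> bool:
        return self.target is None or self.remaining <= 1e-9


def start_walk(plan: FloorPlan, space: str, target: str) -> Position:
    """Begin a walk from ``space`` toward ``target`` along the shortest path."""
    if space == target:
        return Position(space=space)
    route = plan.route(space, target)
    return Position(
        space=space,
        target=target,
        path=route[1:],
        into_edge=0.0,
        remaining=plan.distance(space, target),
    )


def advance(plan: FloorPlan, position: Position, target: str, step_meters: float) -> Position:
    """Move ``step_meters`` along the shortest path toward ``target``.

    The remaining distance decreases by exactly
    ``min(step_meters, remaining)``; the position clamps at the target.
    Returns the updated position (mutated in place for convenience).
    """
    if position.target != target:
        position = start_walk(plan, position.space, target)
    if position.arrived:
        position.space = target
        position.target = None
        position.path = []
        position.into_edge = 0.0
        position.remaining = 0.0
        return position
    step = min(step_meters, position.remaining)
    position.remaining -= step
    position.into_edge += step
    while position.path:
        edge_len = plan.edge_length(position.space, position.path[0])
        if position.into_edge + 1e-9 < edge_len:
            break
        position.into_edge -= edge_len
        position.space = position.path.pop(0)
    if position.remaining <= 1e-9:
        position.space = target
        position.target = None
        position.path = []
        position.into_edge = 0.0
        position.remaining = 0.0
    return position


# ---------------------------------------------------------------------------
# Default ward layout
# ---------------------------------------------------------------------------


def build_default_plan(
    n_rooms: int = 13,
    department: str = "dept",
    remote_walk_meters: Optional[dict] = None,
) -> FloorPlan:
    """Synthetic default ward: a corridor spine with 13 two-bed rooms, a
    sanitary space per room, a nursing post, a head-nurse office, and three
    remote spaces (smoking area, cafeteria, CT scanner).

    The remote one-way walk distances default to 120/180/150 m (i.e. 120,
    180 and 150 s at 1 m/s); no measured values are available, so
    these are repo-authored defaults and fully configurable.
    """
    remote_walk_meters = remote_walk_meters or {
        "smoking_area": 120.0,
        "cafeteria": 180.0,
        "ct_scanner": 150.0,
    }
    spaces: list[Space] = []
    edges: list[tuple] = []
    for i in range(1, n_rooms + 1):
        corridor = f"corridor_{i}"
        room = f"room_{i}"
        san = f"sanitary_{i}"
        spaces.append(Space(corridor, SpaceKind.CORRIDOR, department=department))
        spaces.append(
            Space(room, SpaceKind.PATIENT_ROOM, has_fixed_button=True, department=department)
        )
        spaces.append(
            Space(san, SpaceKind.SANITARY, has_fixed_button=True, department=department)
        )
        edges.append((corridor, room, 3.0))
        edges.append((room, san, 2.0))
        if i > 1:
            edges.append((f"corridor_{i - 1}", corridor, 4.0))
    mid = f"corridor_{(n_rooms + 1) // 2}"
    spaces.append(Space("nursing_post", SpaceKind.NURSING_POST, department=department))
    spaces.append(Space("office", SpaceKind.OFFICE, department=department))
    edges.append((mid, "nursing_post", 5.0))
    edges.append(("nursing_post", "office", 3.0))
    exit_node = f"corridor_{n_rooms}"
    for name, dist in remote_walk_meters.items():
        spaces.append(Space(name, SpaceKind.REMOTE, department=None))
        edges.append((exit_node, name, float(dist)))
    return FloorPlan(spaces, edges)
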