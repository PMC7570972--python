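"""Daily trajectory construction: segmentation, cell mapping, and imputation.

An event log is split into calendar days; each day's events are mapped to grid
cells through the sensor placement, consecutive repeats are collapsed (keeping
dwell bookkeeping), and gaps between non-adjacent observations are filled with
imputed cells so every consecutive pair in the final path is 8-adjacent.  The
imputation rule is greedy: from the current cell, insert the traversable
neighbor x minimizing d(current, x) + d(x, goal) (Euclidean, between cell
centers, in grid units); ties prefer the candidate closer to the goal, then
smaller row, then smaller column.  On an open grid this reproduces the
shortest 8-connected path; a BFS fallback covers concave obstacles where the
greedy rule would cycle.
"""

from __future__ import annotations

import datetime as _dt
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .gridworld import Action, MdpModel, State, action_between, neighbors
from .sensor_io import Cell, Floorplan, SensorEvent

__all__ = [
    "PathPoint",
    "CellPath",
    "Trajectory",
    "PathError",
    "segment_days",
    "events_to_cellpath",
    "impute_path",
    "complete_path",
    "build_trajectory",
]

DAY_SECONDS = 86400


class PathError(ValueError):
    """No traversable route exists between two cells."""


@dataclass(frozen=True)
class PathPoint:
    timestamp: _dt.datetime
    cell: Cell
    source: str = "observed"  # "observed" | "imputed"
    n_events: int = 0  # sensor events collapsed into this point


@dataclass
class CellPath:
    """One day of timestamped cell occupancy.

    Occupancy is piecewise constant: the cell of point *i* is occupied from its
    timestamp until the next point's timestamp, with the first point extended
    back to 00:00:00 and the last forward to 24:00:00, so dwell times tile the
    whole day.
    """

    date: _dt.date
    points: list[PathPoint] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_observed(self) -> int:
        return sum(1 for p in self.points if p.source == "observed")

    @property
    def total_events(self) -> int:
        return sum(p.n_events for p in self.points)

    def dwell_seconds(self) -> list[float]:
        """Per-point dwell durations; sums to 86,400 for a non-empty path."""
        if not self.points:
            return []
        day_start = _dt.datetime.combine(self.date, _dt.time.min)
        bounds = [max(0.0, (p.timestamp - day_start).total_seconds()) for p in self.points]
        bounds.append(float(DAY_SECONDS))
        bounds[0] = 0.0  # first cell back-extended to midnight
        return [bounds[i + 1] - bounds[i] for i in range(len(self.points))]


@dataclass
class Trajectory:
    """One day as a (state, action) sequence — the unit τ of IRL computation."""

    date: _dt.date
    steps: list[tuple[State, Action]] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def segment_days(
    events: Sequence[SensorEvent],
) -> dict[_dt.date, list[SensorEvent]]:
    """Group time-sorted events by calendar day; empty days are absent."""
    out: dict[_dt.date, list[SensorEvent]] = {}
    for e in events:
        out.setdefault(e.timestamp.date(), []).append(e)
    return out


def events_to_cellpath(
    day_events: Sequence[SensorEvent], floorplan: Floorplan
) -> tuple[CellPath, int]:
    """Map one day's events to an observed-only cell path.

    Events from sensors without a placement are skipped (counted, not fatal).
    Consecutive events in the same cell collapse to the first occurrence's
    timestamp; their event counts accumulate on the retained point, so total
    dwell and event counts are conserved.
    """
    if not day_events:
        raise ValueError("day_events must be non-empty")
    date = day_events[0].timestamp.date()
    points: list[PathPoint] = []
    skipped = 0
    for e in day_events:
        cell = floorplan.sensor_cell.get(e.sensor_id)
        if cell is None:
            skipped += 1
            continue
        if points and points[-1].cell == cell:
            prev = points[-1]
            points[-1] = PathPoint(prev.timestamp, cell, "observed", prev.n_events + 1)
        else:
            points.append(PathPoint(e.timestamp, cell, "observed", 1))
    return CellPath(date=date, points=points), skipped


def _dist(a: Cell, b: Cell) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _adjacent(a: Cell, b: Cell) -> bool:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1


def _bfs_path(cell_a: Cell, cell_b: Cell, floorplan: Floorplan) -> list[Cell]:
    """Shortest 8-connected path (interior cells only) via breadth-first search."""
    prev: dict[Cell, Cell] = {cell_a: cell_a}
    queue = deque([cell_a])
    while queue:
        cur = queue.popleft()
        if cur == cell_b:
            path = [cur]
            while prev[path[-1]] != path[-1]:
                path.append(prev[path[-1]])
            return path[::-1][1:-1]
        for nb in sorted(neighbors(floorplan, cur)):
            if nb not in prev:
                prev[nb] = cur
                queue.append(nb)
    raise PathError(f"no traversable route from {cell_a} to {cell_b}")


def impute_path(cell_a: Cell, cell_b: Cell, floorplan: Floorplan) -> list[Cell]:
    """Intermediate cells making ``cell_a → … → cell_b`` 8-connected.

    Greedy minimum-summed-distance insertion (see module docstring); returns
    ``[]`` when the two cells are already adjacent or identical.  Raises
    :class:`PathError` if the cells are disconnected.
    """
    for cell in (cell_a, cell_b):
        if not floorplan.traversable(cell):
            raise PathError(f"cell {cell} is not traversable")
    out: list[Cell] = []
    current = cell_a
    cap = floorplan.n_traversable
    visited = {current}
    while not _adjacent(current, cell_b):
        candidates = neighbors(floorplan, current)
        if not candidates:
            raise PathError(f"no traversable route from {cell_a} to {cell_b}")
        best = min(
            candidates,
            key=lambda x: (
                _dist(current, x) + _dist(x, cell_b),
                _dist(x, cell_b),
                x[0],
                x[1],
            ),
        )
        if best in visited or len(out) > cap:
            # greedy rule cycled (concave obstacle): fall back to BFS
            return _bfs_path(cell_a, cell_b, floorplan)
        visited.add(best)
        out.append(best)
        current = best
    return out


def complete_path(
    cellpath: CellPath, floorplan: Floorplan, walk_seconds_per_cell: float = 3.0
) -> CellPath:
    """Insert imputed points so consecutive cells are 8-adjacent.

    Imputed points are flagged ``source="imputed"`` with zero events.  Their
    timestamps place the walk just before the next observation — the resident
    is assumed to remain at the last observed cell until departing at a
    nominal walking pace (``walk_seconds_per_cell``) — so dwell time stays
    attributed to the occupied cell rather than leaking onto transit cells.
    When the observed gap is shorter than the walk would take, the gap is
    spread evenly instead.
    """
    pts = cellpath.points
    if len(pts) < 2:
        return CellPath(cellpath.date, list(pts))
    out: list[PathPoint] = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        missing = impute_path(a.cell, b.cell, floorplan)
        if missing:
            span = (b.timestamp - a.timestamp).total_seconds()
            m = len(missing)
            step = min(walk_seconds_per_cell, span / (m + 1))
            for i, cell in enumerate(missing, start=1):
                t = b.timestamp - _dt.timedelta(seconds=step * (m - i + 1))
                out.append(PathPoint(t.replace(microsecond=0), cell, "imputed", 0))
        out.append(b)
    return CellPath(cellpath.date, out)


def build_trajectory(cellpath: CellPath, mdp: MdpModel) -> Trajectory:
    """(state, action) steps from an 8-connected cell path.

    Each point becomes a state (cell, time slot of its timestamp); the action
    of step *i* is the move taking cell *i* to cell *i+1*; the final action is
    STAY.  The number of steps equals the number of path points (capped by the
    model's per-day horizon cap).
    """
    pts = cellpath.points[: mdp.horizon_cap]
    steps: list[tuple[State, Action]] = []
    for i, p in enumerate(pts):
        state = State(p.cell, mdp.slot_of(p.timestamp))
        if i + 1 < len(pts):
            action = action_between(p.cell, pts[i + 1].cell)
        else:
            action = Action.STAY
        steps.append((state, action))
    return Trajectory(date=cellpath.date, steps=steps)
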