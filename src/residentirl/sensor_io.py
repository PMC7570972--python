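"""Reading and writing CASAS-style ambient sensor event logs and floorplan configs.

A CASAS event log is plain text, one sensor message per line::

    2009-02-06 17:52:28 M025 ON

i.e. timestamp (date + time), sensor identifier, message.  Both the classic
``MM/DD/YYYY HH:MM:SS`` dialect and ISO ``YYYY-MM-DD HH:MM:SS[.ffffff]`` are
accepted on input; output is always ISO at whole-second resolution.

A floorplan config is a YAML (or JSON) document describing the occupancy grid
a home is quantized into: grid dimensions, cell size, blocked cells, sensor
placements and functional-area labels.  Grid coordinates are 1-based
``(row, col)`` with row 1 at the top of the plan.
"""

from __future__ import annotations

import datetime as _dt
import io
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import yaml

__all__ = [
    "LOCATION_CATEGORIES",
    "SensorEvent",
    "RejectRecord",
    "ParseResult",
    "Floorplan",
    "FloorplanError",
    "parse_events",
    "write_events",
    "write_rejects",
    "load_floorplan",
    "floorplan_to_dict",
]

#: Fixed vocabulary of functional-area labels a grid cell may carry.
LOCATION_CATEGORIES = frozenset(
    {
        "toilet",
        "bathroom_sink",
        "livingroom_chair",
        "kitchen_sink",
        "bedroom",
        "kitchen",
        "livingroom",
        "hallway",
        "stove",
        "office_chair",
        "other",
    }
)

Cell = tuple[int, int]


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor message (timestamp, sensor id, message)."""

    timestamp: _dt.datetime
    sensor_id: str
    message: str

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")
        if self.timestamp.microsecond:
            # sub-second stamps are truncated to whole seconds
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(microsecond=0)
            )


@dataclass(frozen=True)
class RejectRecord:
    """A malformed log line, kept for the reject report instead of being dropped."""

    line_no: int
    line: str
    reason: str


@dataclass
class ParseResult:
    """Outcome of parsing an event log: events in input order plus rejects."""

    events: list[SensorEvent] = field(default_factory=list)
    rejects: list[RejectRecord] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        """Non-blank input lines seen (= len(events) + len(rejects))."""
        return len(self.events) + len(self.rejects)


_TS_FORMATS = (
    "%Y-%m-%d %H:%M:%S.%f",
    "%Y-%m-%d %H:%M:%S",
    "%m/%d/%Y %H:%M:%S.%f",
    "%m/%d/%Y %H:%M:%S",
)


def _parse_timestamp(date_tok: str, time_tok: str) -> _dt.datetime:
    text = f"{date_tok} {time_tok}"
    for fmt in _TS_FORMATS:
        try:
            return _dt.datetime.strptime(text, fmt).replace(microsecond=0)
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp {text!r}")


def parse_events(stream: Union[str, IO[str]]) -> ParseResult:
    """Parse a CASAS event log into events (input order) plus a reject report.

    Each non-blank line must have at least four whitespace-separated fields:
    date, time, sensor id, message (the message may itself contain spaces).
    Malformed lines become :class:`RejectRecord` entries rather than being
    silently dropped; blank lines are skipped.  Events are *not* reordered.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    result = ParseResult()
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) < 4:
            result.rejects.append(
                RejectRecord(line_no, line, "expected date, time, sensor id, message")
            )
            continue
        try:
            ts = _parse_timestamp(tokens[0], tokens[1])
        except ValueError as exc:
            result.rejects.append(RejectRecord(line_no, line, str(exc)))
            continue
        result.events.append(SensorEvent(ts, tokens[2], " ".join(tokens[3:])))
    return result


def write_events(events: Iterable[SensorEvent]) -> str:
    """Serialize events one per line in the standard log layout (ISO timestamps)."""
    return "".join(
        f"{e.timestamp:%Y-%m-%d %H:%M:%S} {e.sensor_id} {e.message}\n" for e in events
    )


def write_rejects(rejects: Iterable[RejectRecord]) -> str:
    """Reject report as TSV: line number, reason, offending line."""
    header = "line_no\treason\tline\n"
    return header + "".join(f"{r.line_no}\t{r.reason}\t{r.line}\n" for r in rejects)


class FloorplanError(ValueError):
    """Raised when a floorplan config violates a structural invariant."""


_NEIGHBOR_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class Floorplan:
    """Occupancy-grid geometry of a home.

    ``location_of`` carries the *base* (disjoint) functional-area label of each
    labeled cell; unlabeled traversable cells are implicitly "other".
    """

    n_rows: int
    n_cols: int
    cell_size_m: float = 1.0
    blocked: frozenset[Cell] = frozenset()
    sensor_cell: Mapping[str, Cell] = field(default_factory=dict)
    location_of: Mapping[Cell, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry ---------------------------------------------------------
    def in_grid(self, cell: Cell) -> bool:
        r, c = cell
        return 1 <= r <= self.n_rows and 1 <= c <= self.n_cols

    def traversable(self, cell: Cell) -> bool:
        return self.in_grid(cell) and cell not in self.blocked

    def cells(self) -> Iterable[Cell]:
        """All traversable cells, row-major."""
        for r in range(1, self.n_rows + 1):
            for c in range(1, self.n_cols + 1):
                if (r, c) not in self.blocked:
                    yield (r, c)

    @property
    def n_traversable(self) -> int:
        return self.n_rows * self.n_cols - len(self.blocked)

    def label(self, cell: Cell) -> str:
        return self.location_of.get(cell, "other")

    def cells_of(self, category: str) -> list[Cell]:
        return [c for c, lab in self.location_of.items() if lab == category]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise FloorplanError("grid dimensions must be positive")
        if self.cell_size_m <= 0:
            raise FloorplanError("cell_size_m must be positive")
        for cell in self.blocked:
            if not self.in_grid(cell):
                raise FloorplanError(f"blocked cell {cell} outside the grid")
        for sid, cell in self.sensor_cell.items():
            if not self.in_grid(cell):
                raise FloorplanError(f"sensor {sid} placed outside the grid at {cell}")
            if cell in self.blocked:
                raise FloorplanError(f"sensor {sid} placed on blocked cell {cell}")
        for cell, lab in self.location_of.items():
            if not self.in_grid(cell):
                raise FloorplanError(f"labeled cell {cell} outside the grid")
            if lab not in LOCATION_CATEGORIES:
                raise FloorplanError(f"unknown location label {lab!r} at {cell}")
        self._check_connected()

    def _check_connected(self) -> None:
        cells = list(self.cells())
        if not cells:
            raise FloorplanError("no traversable cells")
        seen = {cells[0]}
        queue = deque([cells[0]])
        while queue:
            r, c = queue.popleft()
            for dr, dc in _NEIGHBOR_OFFSETS:
                nb = (r + dr, c + dc)
                if self.traversable(nb) and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        if len(seen) != len(cells):
            raise FloorplanError(
                "traversable cells are not 8-connected "
                f"({len(seen)} reachable of {len(cells)})"
            )


def _as_cell(value) -> Cell:
    r, c = value
    return (int(r), int(c))


def load_floorplan(source: Union[str, Path, IO[str], Mapping]) -> Floorplan:
    """Load and validate a floorplan from YAML/JSON text, a path, or a dict.

    Schema::

        grid: {rows: 6, cols: 9, cell_size_m: 1.0}
        blocked: [[2, 5], [3, 5]]
        sensors: {M007: [3, 2], M004: [2, 4]}
        locations:
          bedroom: [[1, 1], [1, 2]]
          toilet: [[1, 4]]
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str) and "\n" not in source and Path(source).is_file():
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "grid" not in doc:
        raise FloorplanError("floorplan config must be a mapping with a 'grid' section")
    grid = doc["grid"]
    location_of: dict[Cell, str] = {}
    for lab, cell_list in (doc.get("locations") or {}).items():
        for cell in cell_list:
            location_of[_as_cell(cell)] = str(lab)
    return Floorplan(
        n_rows=int(grid["rows"]),
        n_cols=int(grid["cols"]),
        cell_size_m=float(grid.get("cell_size_m", 1.0)),
        blocked=frozenset(_as_cell(c) for c in (doc.get("blocked") or [])),
        sensor_cell={str(k): _as_cell(v) for k, v in (doc.get("sensors") or {}).items()},
        location_of=location_of,
    )


def floorplan_to_dict(plan: Floorplan) -> dict:
    """Inverse of :func:`load_floorplan`: a YAML-serializable config dict."""
    locations: dict[str, list[list[int]]] = {}
    for cell, lab in sorted(plan.location_of.items()):
        locations.setdefault(lab, []).append(list(cell))
    return {
        "grid": {
            "rows": plan.n_rows,
            "cols": plan.n_cols,
            "cell_size_m": plan.cell_size_m,
        },
        "blocked": sorted(list(c) for c in plan.blocked),
        "sensors": {k: list(v) for k, v in sorted(plan.sensor_cell.items())},
        "locations": locations,
    }
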