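"""Synthetic smart-home residents: floorplans, preference-driven movement, logs.

The generator emulates multi-month ambient-sensor collections from a single
resident whose behavior is governed by a known 14-dimensional preference
vector θ*, so the whole pipeline — parsing, trajectory building, feature
extraction, IRL fitting, cohort statistics — is testable end to end with
ground truth.

A simulated day is a sequence of *visits*: a destination functional area is
drawn with probability ∝ schedule(hour, area) · exp(θ*_d(area)/temperature),
the resident walks there cell by cell (greedy shortest steps, a few seconds
per cell), then dwells for an exponentially distributed time.  Motion sensors
fire when a sensed cell is entered; during a dwell the area's sensor fires at
``event_rate`` events per occupied minute, scaled for the four activity areas
by the softmax-normalized exp(θ*_o(area)/temperature) — so duration features
track θ*_d and activity features track θ*_o, with sharper coupling at lower
temperature.  The hourly schedule injects diurnal structure (e.g. bedroom
mass at night) independent of θ*; recovery experiments use schedule-flat
profiles.

Cohort defaults mirror an ambient-monitoring study contrast: residents with
cognitive decline prefer the bedroom; cognitively healthy residents prefer
the living room and kitchen and are more active overall.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FEATURE_NAMES, N_FEATURES
from .sensor_io import Cell, Floorplan, SensorEvent
from .trajectories import CellPath, PathPoint, impute_path

__all__ = [
    "SimProfile",
    "SimCohort",
    "SimHomeResult",
    "make_floorplan",
    "simulate_day",
    "simulate_cohort",
    "recovery_profile",
    "healthy_profile",
    "decline_profile",
    "default_cohort",
]

_FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: The ten functional areas a visit can target (duration-feature categories).
VISIT_CATEGORIES = tuple(name[2:] for name in FEATURE_NAMES[:10])
#: The four areas carrying an activity-level feature.
ACTIVITY_CATEGORIES = tuple(name[2:] for name in FEATURE_NAMES[10:])

DAY_SECONDS = 86400


def theta_from_dict(values: dict[str, float]) -> np.ndarray:
    """Build a 14-vector from feature-name → weight (missing names get 0)."""
    theta = np.zeros(N_FEATURES)
    for name, v in values.items():
        theta[_FEATURE_INDEX[name]] = v
    return theta


@dataclass
class SimProfile:
    """Ground-truth behavioral profile of one simulated resident."""

    theta_true: np.ndarray
    label: str = "healthy"  # {"healthy", "decline"}
    schedule: Optional[np.ndarray] = None  # (24, 10) hour × area weights; None = flat
    move_temperature: float = 0.1
    event_rate: float = 0.3  # expected sensor events per occupied minute
    dwell_mean_minutes: float = 30.0
    step_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if self.theta_true.shape != (N_FEATURES,):
            raise ValueError(f"theta_true must have length {N_FEATURES}")
        if self.move_temperature <= 0:
            raise ValueError("move_temperature must be positive")
        if self.schedule is not None:
            self.schedule = np.asarray(self.schedule, dtype=float)
            if self.schedule.shape != (24, len(VISIT_CATEGORIES)):
                raise ValueError("schedule must be (24, 10)")
            if np.any(self.schedule < 0):
                raise ValueError("schedule weights must be non-negative")
            # normalize rows to sum 1
            self.schedule = self.schedule / self.schedule.sum(axis=1, keepdims=True)


@dataclass
class SimCohort:
    """A set of simulated homes: (floorplan, profile, days) per home."""

    homes: list[tuple[str, Floorplan, SimProfile, int]]
    seed: int = 0
    start_date: _dt.date = _dt.date(2024, 1, 1)


@dataclass
class SimHomeResult:
    home_id: str
    floorplan: Floorplan
    profile: SimProfile
    log_text: str
    events: list[SensorEvent]
    truth_paths: list[CellPath]


# ---------------------------------------------------------------------------
# Floorplan generation

_ZONE_SHAPES = {
    # category -> (height, width) of its rectangular zone
    "bedroom": (2, 2),
    "kitchen": (2, 2),
    "livingroom": (2, 2),
    "hallway": (1, 4),
    "toilet": (1, 1),
    "bathroom_sink": (1, 1),
    "kitchen_sink": (1, 1),
    "stove": (1, 1),
    "livingroom_chair": (1, 1),
    "office_chair": (1, 1),
}


def make_floorplan(
    n_rows: int = 8, n_cols: int = 12, seed: Optional[int] = None
) -> Floorplan:
    """A random open-plan home with all ten functional areas placed.

    Zones are non-overlapping axis-aligned rectangles placed by rejection
    sampling; every labeled cell gets a motion sensor, and a sparse lattice of
    extra sensors covers unlabeled space (so movement is observed but gaps
    remain for the imputation stage to fill).  The grid has no blocked cells,
    hence is always 8-connected.
    """
    rng = np.random.default_rng(seed)
    needed = sum(h * w for h, w in _ZONE_SHAPES.values())
    if n_rows * n_cols < 2 * needed:
        raise ValueError("grid too small to place all functional areas")
    for _attempt in range(200):
        taken: set[Cell] = set()
        location_of: dict[Cell, str] = {}
        ok = True
        for cat in sorted(_ZONE_SHAPES, key=lambda c: -np.prod(_ZONE_SHAPES[c])):
            h, w = _ZONE_SHAPES[cat]
            placed = False
            for _try in range(200):
                r = int(rng.integers(1, n_rows - h + 2))
                c = int(rng.integers(1, n_cols - w + 2))
                zone = {(r + i, c + j) for i in range(h) for j in range(w)}
                # one-cell margin keeps functional areas from abutting
                margin = {
                    (rr + dr, cc + dc)
                    for rr, cc in zone
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                }
                if margin & taken:
                    continue
                taken |= zone
                for cell in zone:
                    location_of[cell] = cat
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not place all functional areas")

    sensors: dict[str, Cell] = {}
    i = 1
    for cell in sorted(location_of):
        sensors[f"M{i:03d}"] = cell
        i += 1
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            if (r, c) not in location_of and (r + c) % 3 == 0:
                sensors[f"MA{i:03d}"] = (r, c)
                i += 1
    return Floorplan(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_m=1.0,
        blocked=frozenset(),
        sensor_cell=sensors,
        location_of=location_of,
    )


# ---------------------------------------------------------------------------
# Day simulation


def _visit_weights(profile: SimProfile) -> np.ndarray:
    d_theta = profile.theta_true[:10]
    return np.exp((d_theta - d_theta.max()) / profile.move_temperature)


def _fidget_factors(profile: SimProfile) -> dict[str, float]:
    o_theta = profile.theta_true[10:]
    w = np.exp((o_theta - o_theta.max()) / profile.move_temperature)
    w = w / w.mean()  # mean 1 so event_rate keeps its scale
    return dict(zip(ACTIVITY_CATEGORIES, w))


def simulate_day(
    profile: SimProfile,
    floorplan: Floorplan,
    date: _dt.date,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SensorEvent], CellPath]:
    """One day of movement and sensor events; returns (events, truth path).

    Deterministic given the seed/generator.  Events are time-ordered within
    00:00:00–23:59:59; the truth path records every occupied cell (collapsing
    consecutive repeats) regardless of sensor coverage.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cat_cells = {cat: floorplan.cells_of(cat) for cat in VISIT_CATEGORIES}
    missing = [c for c, cells in cat_cells.items() if not cells]
    if missing:
        raise ValueError(f"floorplan lacks cells for categories: {missing}")
    base_w = _visit_weights(profile)
    fidget = _fidget_factors(profile)
    day_start = _dt.datetime.combine(date, _dt.time.min)

    def ts(seconds: float) -> _dt.datetime:
        return day_start + _dt.timedelta(seconds=min(int(seconds), DAY_SECONDS - 1))

    events: list[SensorEvent] = []
    truth: list[tuple[float, Cell]] = []
    sensor_at = {cell: sid for sid, cell in floorplan.sensor_cell.items()}

    t = 0.0
    cell = cat_cells["bedroom"][int(rng.integers(len(cat_cells["bedroom"])))]
    truth.append((t, cell))
    on_off = 0

    def emit(cell_: Cell, seconds: float) -> None:
        nonlocal on_off
        sid = sensor_at.get(cell_)
        if sid is not None:
            msg = "ON" if on_off % 2 == 0 else "OFF"
            on_off += 1
            events.append(SensorEvent(ts(seconds), sid, msg))

    emit(cell, t)
    while t < DAY_SECONDS:
        hour = min(23, int(t) // 3600)
        w = base_w.copy()
        if profile.schedule is not None:
            w = w * profile.schedule[hour]
        if w.sum() <= 0:
            w = base_w
        p = w / w.sum()
        cat = VISIT_CATEGORIES[int(rng.choice(len(p), p=p))]
        cells = cat_cells[cat]
        target = cells[int(rng.integers(len(cells)))]
        # walk to the target, one cell at a time
        if target != cell:
            route = impute_path(cell, target, floorplan) + [target]
            for nxt in route:
                t += profile.step_seconds
                if t >= DAY_SECONDS:
                    break
                cell = nxt
                truth.append((t, cell))
                emit(cell, t)
        if t >= DAY_SECONDS:
            break
        # dwell
        dur = float(rng.exponential(profile.dwell_mean_minutes * 60.0))
        dur = min(dur, DAY_SECONDS - t)
        rate = profile.event_rate * fidget.get(cat, 1.0)
        n_ev = int(rng.poisson(dur / 60.0 * rate))
        if n_ev and sensor_at.get(cell) is not None:
            offsets = np.sort(rng.uniform(0.0, dur, size=n_ev))
            for off in offsets:
                emit(cell, t + off)
        t += max(dur, 1.0)

    events.sort(key=lambda e: e.timestamp)  # stable: preserves emission order
    points: list[PathPoint] = []
    for sec, c in truth:
        if points and points[-1].cell == c:
            continue
        points.append(PathPoint(ts(sec), c, "observed", 0))
    return events, CellPath(date=date, points=points)


# ---------------------------------------------------------------------------
# Profiles and cohorts


def recovery_profile(temperature: float = 0.1) -> SimProfile:
    """Schedule-flat profile with a strictly ordered θ* for recovery studies.

    Parent areas (kitchen, living room) carry larger weights than their
    contained fixtures so that the parent-inclusive duration features remain
    ordered like θ*.
    """
    theta = theta_from_dict(
        {
            "d_bedroom": 0.50,
            "d_livingroom": 0.45,
            "d_kitchen": 0.40,
            "d_hallway": 0.35,
            "d_toilet": 0.30,
            "d_office_chair": 0.25,
            "d_bathroom_sink": 0.15,
            "d_livingroom_chair": 0.02,
            "d_kitchen_sink": 0.015,
            "d_stove": 0.005,
            "o_toilet": 0.40,
            "o_livingroom_chair": 0.30,
            "o_kitchen_sink": 0.20,
            "o_office_chair": 0.10,
        }
    )
    return SimProfile(theta_true=theta, label="healthy", move_temperature=temperature)


def _diurnal_schedule() -> np.ndarray:
    """Mild diurnal prior: bedroom mass at night, living areas by day."""
    sched = np.ones((24, len(VISIT_CATEGORIES)))
    bed = VISIT_CATEGORIES.index("bedroom")
    for h in list(range(0, 7)) + [22, 23]:
        sched[h, :] = 0.2
        sched[h, bed] = 5.0
    return sched


def healthy_profile(schedule: bool = True) -> SimProfile:
    theta = theta_from_dict(
        {
            "d_bedroom": 0.30,
            "d_livingroom": 0.50,
            "d_kitchen": 0.45,
            "d_hallway": 0.35,
            "d_toilet": 0.25,
            "d_office_chair": 0.20,
            "d_livingroom_chair": 0.05,
            "d_bathroom_sink": 0.15,
            "d_kitchen_sink": 0.03,
            "d_stove": 0.02,
            "o_toilet": 0.20,
            "o_livingroom_chair": 0.35,
            "o_kitchen_sink": 0.30,
            "o_office_chair": 0.25,
        }
    )
    return SimProfile(
        theta_true=theta,
        label="healthy",
        schedule=_diurnal_schedule() if schedule else None,
        event_rate=0.5,
    )


def decline_profile(schedule: bool = True) -> SimProfile:
    theta = theta_from_dict(
        {
            "d_bedroom": 0.55,
            "d_livingroom": 0.25,
            "d_kitchen": 0.20,
            "d_hallway": 0.30,
            "d_toilet": 0.35,
            "d_office_chair": 0.10,
            "d_livingroom_chair": 0.03,
            "d_bathroom_sink": 0.20,
            "d_kitchen_sink": 0.02,
            "d_stove": 0.01,
            "o_toilet": 0.40,
            "o_livingroom_chair": 0.15,
            "o_kitchen_sink": 0.10,
            "o_office_chair": 0.10,
        }
    )
    return SimProfile(
        theta_true=theta,
        label="decline",
        schedule=_diurnal_schedule() if schedule else None,
        event_rate=0.25,
    )


def default_cohort(
    seed: int = 0, n_days: int = 60, n_homes_per_group: int = 4
) -> SimCohort:
    """The default contrasted cohort: 4 decline + 4 healthy homes, 60 days each."""
    homes = []
    for i in range(n_homes_per_group):
        homes.append(
            (f"decline_{i + 1}", make_floorplan(seed=seed + i), decline_profile(), n_days)
        )
    for i in range(n_homes_per_group):
        homes.append(
            (
                f"healthy_{i + 1}",
                make_floorplan(seed=seed + 100 + i),
                healthy_profile(),
                n_days,
            )
        )
    return SimCohort(homes=homes, seed=seed)


def simulate_home(
    home_id: str,
    floorplan: Floorplan,
    profile: SimProfile,
    n_days: int,
    seed: int,
    start_date: _dt.date = _dt.date(2024, 1, 1),
) -> SimHomeResult:
    from .sensor_io import write_events

    rng = np.random.default_rng(seed)
    events: list[SensorEvent] = []
    paths: list[CellPath] = []
    for d in range(n_days):
        date = start_date + _dt.timedelta(days=d)
        ev, path = simulate_day(profile, floorplan, date, rng=rng)
        events.extend(ev)
        paths.append(path)
    return SimHomeResult(
        home_id=home_id,
        floorplan=floorplan,
        profile=profile,
        log_text=write_events(events),
        events=events,
        truth_paths=paths,
    )


def simulate_cohort(cohort: SimCohort) -> list[SimHomeResult]:
    """Simulate every home in a cohort (each home seeded from the cohort seed)."""
    results = []
    for i, (home_id, plan, profile, n_days) in enumerate(cohort.homes):
        results.append(
            simulate_home(
                home_id, plan, profile, n_days, seed=cohort.seed * 1000 + i,
                start_date=cohort.start_date,
            )
        )
    return results
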