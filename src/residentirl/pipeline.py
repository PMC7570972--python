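"""Glue: event log → daily trajectories with features → fitted preferences."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .gridworld import MdpModel, build_mdp, estimate_transitions
from .relent_irl import IrlConfig, IrlResult, TrajectoryFeatures, fit
from .sensor_io import Floorplan, SensorEvent, parse_events
from .trajectories import (
    build_trajectory,
    complete_path,
    events_to_cellpath,
    segment_days,
)

__all__ = ["HomeData", "prepare_home", "fit_preferences"]


@dataclass
class HomeData:
    """A home's prepared daily trajectories, ready for IRL fitting."""

    floorplan: Floorplan
    mdp: MdpModel
    days: list[TrajectoryFeatures]
    n_skipped_events: int = 0


def prepare_home(
    events: Sequence[SensorEvent] | str,
    floorplan: Floorplan,
    slots_per_day: int = 24,
    gamma: float = 1.0,
) -> HomeData:
    """Segment, impute and featurize an event stream into daily trajectories.

    ``events`` may be a parsed event list or raw log text.  Transition and
    start distributions are estimated empirically from the built trajectories.
    """
    if isinstance(events, str):
        events = parse_events(events).events
    mdp = build_mdp(floorplan, slots_per_day=slots_per_day, gamma=gamma)
    days: list[TrajectoryFeatures] = []
    skipped = 0
    by_day = segment_days(events)
    for date in sorted(by_day):
        path, n_skip = events_to_cellpath(by_day[date], floorplan)
        skipped += n_skip
        if not path.points:
            continue
        full = complete_path(path, floorplan)
        traj = build_trajectory(full, mdp)
        days.append(TrajectoryFeatures.from_day(traj, full, floorplan))
    mdp = estimate_transitions([d.trajectory for d in days], mdp)
    return HomeData(floorplan=floorplan, mdp=mdp, days=days, n_skipped_events=skipped)


def fit_preferences(
    home: HomeData, config: Optional[IrlConfig] = None
) -> IrlResult:
    """Fit the preference vector for a prepared home."""
    return fit(home.days, home.mdp, config)
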