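"""Gridworld MDP\\R over floorplan cells and within-day time slots.

Each state is a spatio-temporal region: a traversable grid cell plus the index
of the time slot the resident occupies it in.  The action set has exactly nine
members — staying put or moving to one of the eight adjacent cells.  Movement
dynamics factorize over cells: ``T`` is a distribution over successor *cells*
given (cell, action), while the time-slot component advances exogenously with
wall-clock time (a trajectory step happens at each observed or imputed cell
change, not on a fixed clock tick).

Actions that would leave the grid or enter a blocked cell clamp to STAY, so
|A| = 9 uniformly across states.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

from .sensor_io import Cell, Floorplan

__all__ = [
    "Action",
    "ACTIONS",
    "State",
    "MdpModel",
    "build_mdp",
    "neighbors",
    "action_between",
    "estimate_transitions",
]


class Action(enum.Enum):
    """The nine movement choices: stay, or one of the eight compass neighbors."""

    STAY = (0, 0)
    N = (-1, 0)
    NE = (-1, 1)
    E = (0, 1)
    SE = (1, 1)
    S = (1, 0)
    SW = (1, -1)
    W = (0, -1)
    NW = (-1, -1)

    @property
    def delta(self) -> tuple[int, int]:
        return self.value


ACTIONS: tuple[Action, ...] = tuple(Action)
N_ACTIONS = len(ACTIONS)  # == 9

_DELTA_TO_ACTION = {a.value: a for a in Action}


class State(NamedTuple):
    cell: Cell
    time_slot: int


def neighbors(floorplan: Floorplan, cell: Cell) -> set[Cell]:
    """Traversable 8-neighbors of a cell (excluding the cell itself)."""
    r, c = cell
    out = set()
    for a in ACTIONS:
        if a is Action.STAY:
            continue
        nb = (r + a.delta[0], c + a.delta[1])
        if floorplan.traversable(nb):
            out.add(nb)
    return out


def action_between(cell_a: Cell, cell_b: Cell) -> Action:
    """The unique action whose nominal move takes ``cell_a`` to ``cell_b``.

    Raises ``ValueError`` for non-adjacent pairs.
    """
    delta = (cell_b[0] - cell_a[0], cell_b[1] - cell_a[1])
    try:
        return _DELTA_TO_ACTION[delta]
    except KeyError:
        raise ValueError(f"cells {cell_a} and {cell_b} are not 8-adjacent") from None


@dataclass
class MdpModel:
    """MDP\\R tuple (S, A, T, γ, D) over a floorplan grid.

    ``T is None`` means deterministic nominal dynamics (an action moves to the
    named neighbor, clamping to STAY at walls); ``D is None`` means a uniform
    start distribution over all states.  :func:`estimate_transitions` replaces
    them with smoothed empirical estimates.
    """

    floorplan: Floorplan
    slots_per_day: int = 24
    gamma: float = 1.0
    horizon_cap: int = 5000  # safety cap on steps per daily trajectory
    T: Optional[dict[tuple[Cell, Action], dict[Cell, float]]] = None
    D: Optional[dict[State, float]] = None

    def __post_init__(self) -> None:
        if self.slots_per_day < 1:
            raise ValueError("slots_per_day must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    # -- state space ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.floorplan.n_traversable * self.slots_per_day

    @property
    def n_actions(self) -> int:
        return N_ACTIONS

    def slot_of(self, timestamp: _dt.datetime) -> int:
        """Time-slot index of a timestamp (slots partition the day evenly)."""
        seconds = (
            timestamp.hour * 3600 + timestamp.minute * 60 + timestamp.second
        )
        return min(self.slots_per_day - 1, seconds * self.slots_per_day // 86400)

    # -- dynamics ---------------------------------------------------------
    def nominal_move(self, cell: Cell, action: Action) -> Cell:
        """Deterministic nominal successor cell (clamps to STAY at walls)."""
        nb = (cell[0] + action.delta[0], cell[1] + action.delta[1])
        return nb if self.floorplan.traversable(nb) else cell

    def transition_probs(self, cell: Cell, action: Action) -> dict[Cell, float]:
        if self.T is not None and (cell, action) in self.T:
            return self.T[(cell, action)]
        return {self.nominal_move(cell, action): 1.0}

    def transition_prob(self, cell: Cell, action: Action, next_cell: Cell) -> float:
        return self.transition_probs(cell, action).get(next_cell, 0.0)

    def start_prob(self, state: State) -> float:
        if self.D is None:
            return 1.0 / self.n_states
        return self.D.get(state, 0.0)


def build_mdp(
    floorplan: Floorplan, slots_per_day: int = 24, gamma: float = 1.0
) -> MdpModel:
    """Construct the MDP\\R for a floorplan with nominal deterministic dynamics."""
    return MdpModel(floorplan=floorplan, slots_per_day=slots_per_day, gamma=gamma)


def estimate_transitions(trajectories: Iterable, mdp: MdpModel) -> MdpModel:
    """Empirical (Laplace-smoothed) T and D from observed daily trajectories.

    T rows are add-1 smoothed frequencies over the observed successor support,
    with the nominal successor always included in the support; D is the
    empirical distribution of each day's first state.  An empty trajectory set
    returns the model unchanged (uniform/nominal).
    """
    trans_counts: dict[tuple[Cell, Action], dict[Cell, int]] = {}
    start_counts: dict[State, int] = {}
    n_days = 0
    for traj in trajectories:
        steps = traj.steps
        if not steps:
            continue
        n_days += 1
        s0 = steps[0][0]
        start_counts[s0] = start_counts.get(s0, 0) + 1
        for (state, action), (next_state, _na) in zip(steps, steps[1:]):
            key = (state.cell, action)
            row = trans_counts.setdefault(key, {})
            row[next_state.cell] = row.get(next_state.cell, 0) + 1
    if n_days == 0:
        return mdp

    T: dict[tuple[Cell, Action], dict[Cell, float]] = {}
    for (cell, action), row in trans_counts.items():
        support = dict(row)
        nominal = mdp.nominal_move(cell, action)
        support.setdefault(nominal, 0)
        total = sum(support.values()) + len(support)  # add-1 over the support
        T[(cell, action)] = {nb: (n + 1) / total for nb, n in support.items()}

    total_days = sum(start_counts.values())
    D = {s: n / total_days for s, n in start_counts.items()}
    return replace(mdp, T=T, D=D)
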