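"""The 14-dimensional per-day behavioral feature vector ϕ_τ and its expectations.

Two feature families describe a day of in-home movement:

* ``d_<area>`` — the fraction of the 24 h day dwelt in cells labeled with that
  functional area (seconds dwelt / 86,400, observed plus interpolated dwell).
* ``o_<area>`` — that day's share of movement/activity attributed to the area:
  (non-STAY steps originating in the area + sensor events observed there)
  divided by the day's total of such steps and events over all cells.

Cell labels are disjoint and features are disjoint by default (dwell at the
kitchen sink counts toward ``d_kitchen_sink`` only), so Σ d_* ≤ 1 exactly and
the preference weights over areas are separately identifiable.  An optional
parent map (:data:`NESTED_PARENTS`) makes dwell in a nested fixture also
accrue to its enclosing room (sink/stove → kitchen, living-room chair →
living room) for analyses that prefer the overlapping reading of the area
vocabulary; note that overlapping features introduce directions of θ that the
data cannot distinguish.

Per-step attribution (each trajectory step carrying its instantaneous d/o
increments) is the primitive; summing steps at γ = 1 reproduces the per-day
vector exactly, and discounted sums give the feature expectations μ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .gridworld import Action
from .sensor_io import Floorplan
from .trajectories import CellPath, Trajectory

__all__ = [
    "FEATURE_NAMES",
    "DURATION_FEATURES",
    "ACTIVITY_FEATURES",
    "DEFAULT_PARENTS",
    "NESTED_PARENTS",
    "FeatureExpectation",
    "step_features",
    "extract_features",
    "feature_expectation",
    "minmax_normalize",
]

#: Fixed feature order; indices into every ϕ and θ vector in the package.
FEATURE_NAMES: tuple[str, ...] = (
    "d_toilet",
    "d_bathroom_sink",
    "d_livingroom_chair",
    "d_kitchen_sink",
    "d_bedroom",
    "d_kitchen",
    "d_livingroom",
    "d_hallway",
    "d_stove",
    "d_office_chair",
    "o_toilet",
    "o_livingroom_chair",
    "o_kitchen_sink",
    "o_office_chair",
)

N_FEATURES = len(FEATURE_NAMES)  # == 14
DURATION_FEATURES = FEATURE_NAMES[:10]
ACTIVITY_FEATURES = FEATURE_NAMES[10:]

_FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: Optional functional-area containment: dwell in a nested fixture also counts
#: for the enclosing room.  Off by default (disjoint features).
NESTED_PARENTS: Mapping[str, str] = {
    "kitchen_sink": "kitchen",
    "stove": "kitchen",
    "livingroom_chair": "livingroom",
}

#: Default parent map: empty, i.e. strictly disjoint features.
DEFAULT_PARENTS: Mapping[str, str] = {}

DAY_SECONDS = 86400.0


def _duration_indices(label: str, parents: Mapping[str, str]) -> list[int]:
    idx = []
    name = f"d_{label}"
    if name in _FEATURE_INDEX:
        idx.append(_FEATURE_INDEX[name])
    parent = parents.get(label)
    if parent is not None:
        pname = f"d_{parent}"
        if pname in _FEATURE_INDEX:
            idx.append(_FEATURE_INDEX[pname])
    return idx


def step_features(
    trajectory: Trajectory,
    cellpath: CellPath,
    floorplan: Floorplan,
    parents: Mapping[str, str] = DEFAULT_PARENTS,
) -> np.ndarray:
    """Per-step feature increments, shape ``(n_steps, 14)``.

    Step *i* of the trajectory corresponds to point *i* of the (completed)
    cell path; its duration increment is that point's dwell / 86,400 and its
    activity increment is (move indicator + event count) / the day's total.
    Column sums equal :func:`extract_features`.
    """
    n = trajectory.n_steps
    out = np.zeros((n, N_FEATURES))
    if n == 0:
        return out
    pts = cellpath.points[:n]
    if len(pts) != n:
        raise ValueError("trajectory and cell path lengths disagree")
    dwell = cellpath.dwell_seconds()[:n]

    activity_total = 0.0
    activity_at: list[tuple[int, str, float]] = []
    for i, ((state, action), point) in enumerate(zip(trajectory.steps, pts)):
        label = floorplan.label(state.cell)
        for j in _duration_indices(label, parents):
            out[i, j] += dwell[i] / DAY_SECONDS
        amount = float(point.n_events) + (0.0 if action is Action.STAY else 1.0)
        if amount:
            activity_total += amount
            activity_at.append((i, label, amount))
    if activity_total > 0:
        for i, label, amount in activity_at:
            name = f"o_{label}"
            j = _FEATURE_INDEX.get(name)
            if j is not None:
                out[i, j] += amount / activity_total
    return out


def extract_features(
    trajectory: Trajectory,
    cellpath: CellPath,
    floorplan: Floorplan,
    parents: Mapping[str, str] = DEFAULT_PARENTS,
) -> np.ndarray:
    """The day's 14-vector ϕ_τ (column sums of the per-step attribution)."""
    return step_features(trajectory, cellpath, floorplan, parents).sum(axis=0)


@dataclass
class FeatureExpectation:
    """μ — mean (discounted) per-trajectory feature sum over a trajectory set."""

    mu: np.ndarray
    n_trajectories: int
    gamma: float


def feature_expectation(
    step_matrices: Sequence[np.ndarray], gamma: float = 1.0
) -> FeatureExpectation:
    """μ = mean over trajectories of Σ_i γ^i ϕ(s_i, a_i).

    At γ = 1 this is the plain mean of per-trajectory feature totals; at γ = 0
    only each day's first step contributes.
    """
    if not step_matrices:
        raise ValueError("need at least one trajectory")
    totals = []
    for mat in step_matrices:
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != N_FEATURES:
            raise ValueError(f"step matrix must be (n_steps, {N_FEATURES})")
        if gamma == 1.0:
            totals.append(mat.sum(axis=0))
        else:
            weights = gamma ** np.arange(mat.shape[0])
            totals.append(weights @ mat)
    mu = np.mean(totals, axis=0)
    return FeatureExpectation(mu=mu, n_trajectories=len(step_matrices), gamma=gamma)


def minmax_normalize(theta: np.ndarray) -> np.ndarray:
    """Per-vector min-max rescaling to [0, 1] (the reporting convention).

    A constant vector has no ordering information; it maps to all 0.5 with a
    warning.
    """
    theta = np.asarray(theta, dtype=float)
    lo, hi = theta.min(), theta.max()
    if hi - lo <= 0:
        warnings.warn("constant preference vector; min-max normalization undefined")
        return np.full_like(theta, 0.5)
    return (theta - lo) / (hi - lo)
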