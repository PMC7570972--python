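"""Relative-entropy inverse reinforcement learning over daily trajectories.

The model: among all trajectory distributions P, pick the one closest in
KL divergence to a baseline distribution Q subject to matching the observed
feature expectations μ within per-feature slack ε (a Hoeffding-style bound).
The solution is the exponential-family tilt

    P(τ|θ) = Q(τ) exp(θ·ϕ_τ) / Z(θ),   Z(θ) = Σ_τ Q(τ) exp(θ·ϕ_τ),

and θ maximizes the Lagrange dual

    g(θ) = θ·μ − ln Z(θ) − Σ_i ε_i |θ_i|,

whose gradient is ∂g/∂θ_i = μ_i − E_{P(·|θ)}[ϕ_i] − σ_i ε_i with
σ_i = sign(θ_i) (taken +1 at zero).  Z and its gradient are estimated by
self-normalized importance sampling over a set of sample trajectories drawn
from a sampling policy π̂; when the samples are baseline-policy rollouts the
weights reduce to exp(θ·ϕ_τ).  Fitting is plain (sub)gradient ascent with a
per-feature learning rate, stopping when every |∂g/∂θ_i| falls below ε_i.

All probability arithmetic is in log space with max-subtraction.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .features import (
    N_FEATURES,
    FeatureExpectation,
    extract_features,
    feature_expectation,
    step_features,
)
from .gridworld import ACTIONS, Action, MdpModel, State, action_between, neighbors
from .sensor_io import Cell, Floorplan
from .trajectories import CellPath, PathPoint, Trajectory

__all__ = [
    "BaselinePolicy",
    "RoutineBaseline",
    "IrlConfig",
    "IrlResult",
    "TrajectoryFeatures",
    "trajectory_reward",
    "baseline_logprob",
    "trajectory_prob",
    "hoeffding_epsilon",
    "bernstein_epsilon",
    "dual_value",
    "dual_gradient",
    "rollout_baseline",
    "fit",
]


def trajectory_reward(theta: np.ndarray, phi_tau: np.ndarray) -> float:
    """Linear trajectory reward θ·ϕ_τ."""
    theta = np.asarray(theta, dtype=float)
    phi_tau = np.asarray(phi_tau, dtype=float)
    if theta.shape != phi_tau.shape:
        raise ValueError("theta and phi must have equal length")
    return float(theta @ phi_tau)


class BaselinePolicy:
    """Uniform baseline over the valid moves of each cell.

    The baseline measure Q(τ) factors as Stran(τ)·Atran(τ): start distribution
    and transition probabilities of the MDP times the product of per-step
    action probabilities.  The action distribution is uniform over STAY plus
    the traversable neighbors, so its per-state probabilities sum to one and
    baseline rollouts are drawn exactly from Q.
    """

    def __init__(self, floorplan: Floorplan):
        self.floorplan = floorplan
        self._valid: dict[Cell, tuple[Cell, ...]] = {}

    def valid_moves(self, cell: Cell) -> tuple[Cell, ...]:
        moves = self._valid.get(cell)
        if moves is None:
            moves = (cell,) + tuple(sorted(neighbors(self.floorplan, cell)))
            self._valid[cell] = moves
        return moves

    def log_action_prob(self, cell: Cell, action: Action) -> float:
        moves = self.valid_moves(cell)
        target = (cell[0] + action.delta[0], cell[1] + action.delta[1])
        if action is Action.STAY or target in moves:
            return -math.log(len(moves))
        return -math.inf

    def sample_move(self, cell: Cell, rng: np.random.Generator) -> Cell:
        moves = self.valid_moves(cell)
        return moves[rng.integers(len(moves))]


def baseline_logprob(
    tau: Trajectory, mdp: MdpModel, policy: Optional[BaselinePolicy] = None
) -> float:
    """log Q(τ) = log D(s₀) + Σ log T(sᵢ,aᵢ,sᵢ₊₁) + Σ log π_Q(aᵢ|sᵢ).

    A zero-probability step yields ``-inf`` (the trajectory is outside the
    baseline's support); callers should treat that as a flagged degenerate
    value rather than an error.
    """
    if policy is None:
        policy = BaselinePolicy(mdp.floorplan)
    steps = tau.steps
    if not steps:
        raise ValueError("empty trajectory")
    log_p = math.log(mdp.start_prob(steps[0][0])) if mdp.start_prob(steps[0][0]) > 0 else -math.inf
    for (state, action), (next_state, _na) in zip(steps, steps[1:]):
        t = mdp.transition_prob(state.cell, action, next_state.cell)
        log_p += math.log(t) if t > 0 else -math.inf
        log_p += policy.log_action_prob(state.cell, action)
    # final action (STAY by construction) has no successor but is still chosen
    log_p += policy.log_action_prob(steps[-1][0].cell, steps[-1][1])
    return log_p


def trajectory_prob(
    theta: np.ndarray, Phi: np.ndarray, baseline_logprobs: np.ndarray
) -> np.ndarray:
    """P(τ|θ) ∝ Q(τ)·exp(θ·ϕ_τ) over a trajectory set, normalized to 1.

    ``Phi`` is the (n, k) feature matrix, ``baseline_logprobs`` the log Q
    values.  Computed in log space with max-subtraction; Σ P = 1 to 1e-12.
    """
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    log_q = np.asarray(baseline_logprobs, dtype=float)
    if Phi.shape[0] != log_q.shape[0] or Phi.shape[0] < 1:
        raise ValueError("Phi and baseline_logprobs must share a positive length")
    a = Phi @ np.asarray(theta, dtype=float) + log_q
    if np.all(np.isinf(a) & (a < 0)):
        raise ValueError("all trajectories have zero baseline probability")
    a -= a.max()
    p = np.exp(a)
    return p / p.sum()


def hoeffding_epsilon(
    n_samples: int,
    k: int = N_FEATURES,
    delta: float = 0.05,
    feature_ranges: Union[float, np.ndarray] = 1.0,
) -> np.ndarray:
    """Per-feature constraint slack ε_i = range_i · sqrt(ln(2k/δ) / (2n)).

    This is Hoeffding's deviation bound for the mean of n bounded per-day
    feature values, union-bounded over the k features at confidence 1 − δ.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    scale = math.sqrt(math.log(2 * k / delta) / (2 * n_samples))
    return np.broadcast_to(np.asarray(feature_ranges, dtype=float) * scale, (k,)).copy()


def dual_value(
    theta: np.ndarray,
    mu: Union[np.ndarray, FeatureExpectation],
    Phi: np.ndarray,
    baseline_logprobs: np.ndarray,
    epsilon: np.ndarray,
) -> float:
    """g(θ) = θ·μ − ln Z(θ) − Σ_i ε_i|θ_i| with Z(θ) = Σ_τ Q(τ)exp(θ·ϕ_τ)."""
    theta = np.asarray(theta, dtype=float)
    if isinstance(mu, FeatureExpectation):
        mu = mu.mu
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    a = Phi @ theta + np.asarray(baseline_logprobs, dtype=float)
    return float(theta @ mu - logsumexp(a) - np.asarray(epsilon) @ np.abs(theta))


def dual_gradient(
    theta: np.ndarray,
    mu: Union[np.ndarray, FeatureExpectation],
    Phi: np.ndarray,
    baseline_logprobs: np.ndarray,
    epsilon: np.ndarray,
    sampling_logprobs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """∂g/∂θ_i = μ_i − Σ_τ w(τ)·ϕ_i(τ) − σ_i·ε_i over the sample set T_N.

    w(τ) are self-normalized importance weights ∝ exp(θ·ϕ_τ)·Q(τ)/π̂(τ); with
    ``sampling_logprobs`` omitted, π̂ is taken equal (up to a constant) to the
    distribution the samples were drawn from, i.e. w ∝ exp(θ·ϕ_τ)·Q(τ), which
    makes the gradient the exact derivative of :func:`dual_value` on the same
    inputs.  σ_i = +1 for θ_i ≥ 0, else −1 (the subgradient of |θ_i|).
    An effective sample size below 2 triggers a degenerate-weights warning.
    """
    theta = np.asarray(theta, dtype=float)
    if isinstance(mu, FeatureExpectation):
        mu = mu.mu
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    a = Phi @ theta + np.asarray(baseline_logprobs, dtype=float)
    if sampling_logprobs is not None:
        a = a - np.asarray(sampling_logprobs, dtype=float)
    a -= a.max()
    w = np.exp(a)
    w /= w.sum()
    if Phi.shape[0] > 1 and 1.0 / np.sum(w**2) < 2.0:
        warnings.warn("degenerate importance weights (effective sample size < 2)")
    sigma = np.where(theta >= 0, 1.0, -1.0)
    return np.asarray(mu, dtype=float) - w @ Phi - sigma * np.asarray(epsilon)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class TrajectoryFeatures:
    """A daily trajectory bundled with its features — the unit `fit` consumes.

    ``n_moves`` and ``n_events`` record the day's absolute activity counts
    (non-STAY steps; sensor events), which the activity-share features divide
    away but the routine baseline needs to calibrate its event-rate scale.
    """

    trajectory: Trajectory
    phi: np.ndarray
    step_matrix: np.ndarray
    n_moves: int = 0
    n_events: int = 0
    transit_phi: Optional[np.ndarray] = None  # feature mass from pass-throughs

    #: dwell shorter than this is treated as transit, not a visit
    TRANSIT_CUTOFF_S = 120.0

    @classmethod
    def from_day(
        cls, trajectory: Trajectory, cellpath: CellPath, floorplan: Floorplan
    ) -> "TrajectoryFeatures":
        steps = step_features(trajectory, cellpath, floorplan)
        n_moves = sum(1 for _s, a in trajectory.steps if a is not Action.STAY)
        dwell = np.asarray(cellpath.dwell_seconds()[: steps.shape[0]])
        transit = steps[dwell < cls.TRANSIT_CUTOFF_S].sum(axis=0) if steps.size else steps.sum(axis=0)
        return cls(
            trajectory=trajectory,
            phi=steps.sum(axis=0),
            step_matrix=steps,
            n_moves=n_moves,
            n_events=cellpath.total_events,
            transit_phi=transit,
        )


def bernstein_epsilon(
    Phi_obs: np.ndarray, delta: float = 0.05
) -> np.ndarray:
    """Empirical-Bernstein constraint slack ε_i = σ̂_i · sqrt(2 ln(3k/δ) / n).

    Like the Hoeffding slack but scaled by each feature's observed per-day
    standard deviation instead of its a-priori range, which keeps the
    feature-matching constraints informative for features whose daily values
    occupy a narrow band.  Features with no observed variation fall back to
    the conservative unit range.
    """
    n, k = Phi_obs.shape
    if n < 2:
        return hoeffding_epsilon(n, k, delta, 1.0)
    sd = Phi_obs.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    return sd * math.sqrt(2.0 * math.log(3.0 * k / delta) / n)


@dataclass
class IrlConfig:
    """Configuration of the IRL fit.

    ``epsilon`` — per-feature constraint slack: ``"auto"`` (empirical-Bernstein
    from the observed days), ``"hoeffding"`` (range-based Hoeffding bound with
    ``feature_ranges``), or an explicit 14-vector.

    ``sample_mode`` selects how the partition function Z(θ) is evaluated:

    * ``"routine"`` (default) — closed form under the analytic preference-free
      routine baseline (:class:`RoutineBaseline`); deterministic, no sampling
      noise, valid at any concentration of the observed behavior.
    * ``"rollout"`` — self-normalized importance sampling over fresh
      baseline-policy rollouts from the MDP (length-matched to the observed
      days).
    * ``"observed"`` — importance sampling over a subset of the observed
      trajectories with π̂ estimated from their empirical per-cell action
      frequencies (add-1).

    ``learn_rate`` ``None`` picks a per-mode default (1.0 with backtracking
    for ``"routine"``, 0.05 for the sampled modes).
    """

    delta: float = 0.05
    epsilon: Union[str, np.ndarray] = "auto"
    learn_rate: Union[None, float, np.ndarray] = None
    n_samples: int = 100
    gamma: float = 1.0
    max_iter: int = 2000
    seed: int = 42
    lr_decay: bool = False
    sample_mode: str = "routine"
    feature_ranges: Union[str, float, np.ndarray] = "empirical"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.learn_rate is not None and np.any(np.asarray(self.learn_rate) < 0):
            raise ValueError("learn_rate must be >= 0")
        if self.sample_mode not in ("routine", "rollout", "observed"):
            raise ValueError("sample_mode must be 'routine', 'rollout' or 'observed'")


@dataclass
class IrlResult:
    theta: np.ndarray
    dual_trace: list[float] = field(default_factory=list)
    grad_norm_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    epsilon: Optional[np.ndarray] = None
    degenerate_weights: bool = False


_DAY_SECONDS = 86400.0


@dataclass
class RoutineBaseline:
    """Closed-form preference-free routine baseline over daily trajectories.

    The baseline models a day as ``visits_per_day`` independent visits: each
    visit targets one of the ten functional areas uniformly (``q``), dwells
    for an exponentially distributed time with mean ``dwell_mean_s`` seconds,
    and emits Poisson sensor events at ``event_rate_per_s`` while dwelling.
    Under this model the log partition function of the exponential tilt
    P(τ|θ) ∝ Q(τ)·exp(θ·ϕ_τ) and the tilted feature expectation E_θ[ϕ] are
    available in closed form.  Each visit dwells the typical duration m̄, so
    the per-visit log moment generating function of the feature increment for
    a visit to area c is

        g_c(θ) = s_c·m̄/86400 + r·m̄·(exp(t_c/M) − 1),

    where s_c = Σ_i θ_i·A_ic is the duration weight of dwelling in c, t_c the
    activity weight, r the event rate and M the day's typical activity total.
    The tilted visit distribution is then the softmax of g(θ), so any observed
    mean composition — including strong suppression of rarely visited areas —
    is matched at finite θ.  Everything is smooth and deterministic: no
    importance-sampling noise and no feasibility boundary.
    """

    dur_map: np.ndarray  # (k, 10) duration-feature increment directions
    act_map: np.ndarray  # (k, 10) activity-feature increment directions
    dwell_mean_s: float = 1800.0
    visits_per_day: float = 48.0
    event_rate_per_s: float = 0.005
    activity_scale: float = 500.0  # M: typical per-day activity denominator
    moves_per_visit: float = 2.0
    offset: Optional[np.ndarray] = None  # preference-free transit feature mass
    q: Optional[np.ndarray] = None  # baseline visit distribution (uniform)

    def __post_init__(self) -> None:
        if self.offset is None:
            self.offset = np.zeros(self.dur_map.shape[0])
        if self.q is None:
            self.q = np.full(self.dur_map.shape[1], 1.0 / self.dur_map.shape[1])

    @classmethod
    def from_days(
        cls,
        days: Sequence["TrajectoryFeatures"],
        floorplan: Optional[Floorplan] = None,
        parents=None,
    ) -> "RoutineBaseline":
        """Calibrate the baseline's rate scales from the observed days.

        With a floorplan available, visits are counted as entries into labeled
        areas, the mean dwell per visit and the per-visit move count are
        measured directly; otherwise generic defaults (48 half-hour visits a
        day) are used.
        """
        from .features import (
            DEFAULT_PARENTS,
            FEATURE_NAMES,
            _duration_indices,
        )

        if parents is None:
            parents = DEFAULT_PARENTS
        categories = tuple(n[2:] for n in FEATURE_NAMES[:10])
        k = len(FEATURE_NAMES)
        dur_map = np.zeros((k, len(categories)))
        act_map = np.zeros((k, len(categories)))
        o_index = {n[2:]: i for i, n in enumerate(FEATURE_NAMES) if n.startswith("o_")}
        for j, cat in enumerate(categories):
            for i in _duration_indices(cat, parents):
                dur_map[i, j] = 1.0
            if cat in o_index:
                act_map[o_index[cat], j] = 1.0

        mean_events = float(np.mean([d.n_events for d in days])) if days else 0.0
        mean_moves = float(np.mean([d.n_moves for d in days])) if days else 0.0
        activity = max(1.0, mean_events + mean_moves)

        dwell_mean_s, visits, moves_per_visit = 1800.0, _DAY_SECONDS / 1800.0, 2.0
        if floorplan is not None and days:
            arrivals = 0
            labeled_moves = 0
            for d in days:
                prev_label = None
                for (state, action) in d.trajectory.steps:
                    lab = floorplan.label(state.cell)
                    if lab != "other" and lab != prev_label:
                        arrivals += 1
                    if lab != "other" and action is not Action.STAY:
                        labeled_moves += 1
                    prev_label = lab
            # labeled dwell time: sum of the base-category duration features
            labeled_dwell_s = _DAY_SECONDS * sum(
                float(d.phi[:10].sum()) for d in days
            )
            if arrivals > 0 and labeled_dwell_s > 0:
                dwell_mean_s = max(60.0, labeled_dwell_s / arrivals)
                visits = max(2.0, arrivals / len(days))
                moves_per_visit = max(0.5, labeled_moves / arrivals)

        rate = max(1e-6, mean_events / _DAY_SECONDS)
        # pass-through occupancy and activity do not express dwelling
        # preference; they enter the model as a constant offset
        offset = None
        transits = [d.transit_phi for d in days if d.transit_phi is not None]
        if transits:
            offset = np.mean(transits, axis=0)
        return cls(
            dur_map=dur_map,
            act_map=act_map,
            dwell_mean_s=dwell_mean_s,
            visits_per_day=visits,
            event_rate_per_s=rate,
            activity_scale=activity,
            moves_per_visit=moves_per_visit,
            offset=offset,
        )

    # -- closed-form pieces ----------------------------------------------
    def _log_mgf(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-visit log MGF g_c(θ) by area, plus the activity weights t."""
        s = self.dur_map.T @ theta  # (10,)
        t = self.act_map.T @ theta  # (10,)
        g = (
            s * self.dwell_mean_s / _DAY_SECONDS
            + (self.event_rate_per_s * self.dwell_mean_s)
            * (np.exp(t / self.activity_scale) - 1.0)
            + t * self.moves_per_visit / self.activity_scale
        )
        return g, t

    def log_z(self, theta: np.ndarray) -> float:
        """Per-day log partition function n_v · ln Σ_c q_c·exp(g_c(θ))."""
        g, _ = self._log_mgf(theta)
        return self.visits_per_day * float(logsumexp(g, b=self.q))

    def visit_distribution(self, theta: np.ndarray) -> np.ndarray:
        """Tilted visit-choice distribution: softmax of g(θ) over the areas."""
        g, _ = self._log_mgf(theta)
        a = g + np.log(self.q)
        a -= a.max()
        p = np.exp(a)
        return p / p.sum()

    def expected_features(self, theta: np.ndarray) -> np.ndarray:
        """E_θ[ϕ] under the tilted routine baseline (the gradient of log Z)."""
        g, t = self._log_mgf(theta)
        p = self.visit_distribution(theta)
        events = self.event_rate_per_s * self.dwell_mean_s * np.exp(
            t / self.activity_scale
        )
        per_visit = self.dur_map @ (p * self.dwell_mean_s / _DAY_SECONDS) + (
            self.act_map @ (p * (events + self.moves_per_visit) / self.activity_scale)
        )
        return self.offset + self.visits_per_day * per_visit


_ROLLOUT_DATE = _dt.date(2000, 1, 1)


def rollout_baseline(
    mdp: MdpModel,
    n_steps: int,
    rng: np.random.Generator,
    policy: Optional[BaselinePolicy] = None,
) -> tuple[Trajectory, CellPath]:
    """One baseline-policy rollout of ``n_steps`` steps with synthetic timing.

    The start state is drawn from D (uniform if unestimated); each step picks
    a move uniformly over STAY plus traversable neighbors.  Timestamps are
    spread evenly over the day so the rollout's duration features are the
    fraction of steps spent in each area.
    """
    if policy is None:
        policy = BaselinePolicy(mdp.floorplan)
    if mdp.D is not None:
        states = list(mdp.D.keys())
        probs = np.array([mdp.D[s] for s in states])
        cell = states[rng.choice(len(states), p=probs / probs.sum())].cell
    else:
        cells = list(mdp.floorplan.cells())
        cell = cells[rng.integers(len(cells))]
    day_start = _dt.datetime.combine(_ROLLOUT_DATE, _dt.time.min)
    points: list[PathPoint] = []
    cells_seq: list[Cell] = [cell]
    for _ in range(n_steps - 1):
        cell = policy.sample_move(cell, rng)
        cells_seq.append(cell)
    step_len = 86400.0 / max(1, n_steps)
    steps: list[tuple[State, Action]] = []
    for i, c in enumerate(cells_seq):
        t = day_start + _dt.timedelta(seconds=int(i * step_len))
        points.append(PathPoint(t, c, "imputed", 0))
        action = (
            action_between(c, cells_seq[i + 1]) if i + 1 < len(cells_seq) else Action.STAY
        )
        steps.append((State(c, mdp.slot_of(t)), action))
    return Trajectory(date=_ROLLOUT_DATE, steps=steps), CellPath(_ROLLOUT_DATE, points)


def _empirical_action_logprobs(
    trajs: Sequence[Trajectory], policy: BaselinePolicy
) -> np.ndarray:
    """Per-trajectory Σ log π̂(a|cell), π̂ = add-1 empirical action frequencies."""
    counts: dict[Cell, dict[Action, int]] = {}
    for tau in trajs:
        for state, action in tau.steps:
            row = counts.setdefault(state.cell, {})
            row[action] = row.get(action, 0) + 1
    out = np.zeros(len(trajs))
    for j, tau in enumerate(trajs):
        total = 0.0
        for state, action in tau.steps:
            row = counts[state.cell]
            n_valid = len(policy.valid_moves(state.cell))
            total += math.log(
                (row.get(action, 0) + 1) / (sum(row.values()) + n_valid)
            )
        out[j] = total
    return out


def _slack_vector(config: IrlConfig, Phi_obs: np.ndarray) -> np.ndarray:
    if isinstance(config.epsilon, str):
        if config.epsilon == "auto":
            return bernstein_epsilon(Phi_obs, config.delta)
        if config.epsilon == "hoeffding":
            ranges = config.feature_ranges
            if isinstance(ranges, str) and ranges == "empirical":
                r = Phi_obs.max(axis=0) - Phi_obs.min(axis=0)
                r[r <= 0] = 1.0  # no observed variation: a-priori width
                ranges = r
            return hoeffding_epsilon(
                Phi_obs.shape[0], N_FEATURES, config.delta, ranges
            )
        raise ValueError(f"unknown epsilon mode {config.epsilon!r}")
    return np.broadcast_to(
        np.asarray(config.epsilon, dtype=float), (N_FEATURES,)
    ).copy()


def _fit_routine(
    days: Sequence[TrajectoryFeatures],
    mdp: MdpModel,
    mu: np.ndarray,
    eps: np.ndarray,
    config: IrlConfig,
    rng: np.random.Generator,
) -> IrlResult:
    """Gradient ascent on the closed-form routine-baseline dual, with
    backtracking to respect the feasible tilt region and keep the trace
    monotone."""
    baseline = RoutineBaseline.from_days(days, floorplan=mdp.floorplan)
    alpha = 1.0 if config.learn_rate is None else config.learn_rate
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (N_FEATURES,))

    def value(th: np.ndarray) -> float:
        # the constant transit offset contributes a linear term to ln Z
        lz = baseline.log_z(th) + float(th @ baseline.offset)
        if not math.isfinite(lz):
            return -math.inf
        return float(th @ mu - lz - eps @ np.abs(th))

    def generalized_grad(th: np.ndarray, smooth: np.ndarray) -> np.ndarray:
        """Min-norm subgradient of g: the smooth part minus the best ε·∂|θ|."""
        out = smooth - np.where(th > 0, 1.0, -1.0) * eps
        at_kink = th == 0
        shrunk = np.sign(smooth) * np.maximum(np.abs(smooth) - eps, 0.0)
        out[at_kink] = shrunk[at_kink]
        return out

    theta = rng.normal(0.0, 0.01, size=N_FEATURES)
    result = IrlResult(theta=theta, epsilon=eps)
    for t in range(1, config.max_iter + 1):
        smooth = mu - baseline.expected_features(theta)
        grad = generalized_grad(theta, smooth)
        if not np.all(np.isfinite(grad)):
            raise RuntimeError(f"non-finite gradient at iteration {t}: {grad}")
        g0 = value(theta)
        result.dual_trace.append(g0)
        result.grad_norm_trace.append(float(np.max(np.abs(grad))))
        result.iterations = t
        if np.all(np.abs(grad) <= eps):
            result.converged = True
            break
        if np.all(alpha == 0):
            continue
        # proximal ascent: gradient step on the smooth part, then the exact
        # soft-threshold prox of the ε·|θ| penalty; backtrack to keep the
        # dual non-decreasing
        scale = 1.0 / math.sqrt(t) if config.lr_decay else 1.0
        moved = False
        while scale > 1e-12:
            y = theta + scale * alpha * smooth
            cand = np.sign(y) * np.maximum(np.abs(y) - scale * alpha * eps, 0.0)
            if value(cand) > g0:
                theta = cand
                moved = True
                break
            scale *= 0.5
        if not moved:
            result.converged = True  # proximal fixpoint at numeric resolution
            break
    result.theta = theta
    return result


def _fit_sampled(
    days: Sequence[TrajectoryFeatures],
    mdp: MdpModel,
    mu: np.ndarray,
    eps: np.ndarray,
    config: IrlConfig,
    rng: np.random.Generator,
) -> IrlResult:
    """Plain gradient ascent with the importance-sampled dual gradient."""
    policy = BaselinePolicy(mdp.floorplan)
    if config.sample_mode == "rollout":
        lengths = np.array([max(2, d.trajectory.n_steps) for d in days])
        n_roll = max(2, config.n_samples)
        Phi_N = np.empty((n_roll, N_FEATURES))
        log_q = np.empty(n_roll)
        log_pihat = np.empty(n_roll)
        for i in range(n_roll):
            L = int(lengths[rng.integers(len(lengths))])
            traj, path = rollout_baseline(mdp, L, rng, policy)
            Phi_N[i] = extract_features(traj, path, mdp.floorplan)
            lq = baseline_logprob(traj, mdp, policy)
            log_q[i] = lq
            log_pihat[i] = lq  # rollouts are drawn exactly from Q
    else:
        n_sub = min(len(days), config.n_samples)
        idx = rng.choice(len(days), size=n_sub, replace=False)
        subset = [days[i] for i in idx]
        Phi_N = np.vstack([d.phi for d in subset])
        log_q = np.array([baseline_logprob(d.trajectory, mdp, policy) for d in subset])
        log_pihat = _empirical_action_logprobs([d.trajectory for d in subset], policy)

    log_q_eff = log_q - log_pihat  # importance correction (zero for rollouts)
    alpha = 0.05 if config.learn_rate is None else config.learn_rate
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (N_FEATURES,))

    theta = rng.normal(0.0, 0.01, size=N_FEATURES)
    result = IrlResult(theta=theta, epsilon=eps)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for t in range(1, config.max_iter + 1):
            grad = dual_gradient(theta, mu, Phi_N, log_q_eff, eps)
            if not np.all(np.isfinite(grad)):
                raise RuntimeError(f"non-finite gradient at iteration {t}: {grad}")
            result.dual_trace.append(dual_value(theta, mu, Phi_N, log_q_eff, eps))
            result.grad_norm_trace.append(float(np.max(np.abs(grad))))
            result.iterations = t
            if np.all(np.abs(grad) <= eps):
                result.converged = True
                break
            lr = alpha / math.sqrt(t) if config.lr_decay else alpha
            theta = theta + lr * grad
    result.degenerate_weights = any(
        "effective sample size" in str(w.message) for w in caught
    )
    result.theta = theta
    return result


def fit(
    days: Sequence[TrajectoryFeatures],
    mdp: MdpModel,
    config: Optional[IrlConfig] = None,
) -> IrlResult:
    """Learn the preference vector θ from a resident's daily trajectories.

    Gradient ascent on the dual g(θ) from a small random initialization,
    θ_i ← θ_i + α_i·∂g/∂θ_i, stopping when every |∂g/∂θ_i| ≤ ε_i or after
    ``max_iter`` iterations.  The default evaluates Z(θ) in closed form under
    the preference-free routine baseline; the sampled modes fix T_N once per
    fit, so the dual trace is (up to subgradient kinks) non-decreasing.
    """
    if config is None:
        config = IrlConfig()
    if not days:
        raise ValueError("need at least one trajectory")
    rng = np.random.default_rng(config.seed)
    Phi_obs = np.vstack([d.phi for d in days])
    mu = feature_expectation([d.step_matrix for d in days], gamma=config.gamma).mu
    eps = _slack_vector(config, Phi_obs)
    if config.sample_mode == "routine":
        return _fit_routine(days, mdp, mu, eps, config, rng)
    return _fit_sampled(days, mdp, mu, eps, config, rng)
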