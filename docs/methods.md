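# Methods

This note documents the models implemented in `residentirl`, the choices
made where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## The floorplan MDP

A home is quantized into an `n_rows × n_cols` grid of equal cells (1-based
`(row, col)` coordinates, row 1 at the top).  A state is a spatio-temporal
region: a traversable cell plus the index of a within-day time slot
(default 24 hourly slots; configurable).  The action set always has nine
members — STAY plus the eight compass moves; actions that would leave the
grid or enter a blocked cell clamp to STAY rather than being removed, so
|A| = 9 uniformly.

Transition structure is factorized: T is a distribution over successor
*cells* given (cell, action), while the time-slot component advances with
wall-clock time.  A trajectory step happens at each observed or imputed cell
change (event-driven, not clock-ticked), capped at 5000 steps per day as a
safety bound.  `estimate_transitions` replaces the nominal deterministic
dynamics with add-1-smoothed empirical frequencies and an empirical start
distribution; because observed trajectories are built with `action_between`,
the empirical rows coincide with the nominal moves and the estimate mainly
contributes the start distribution.

## Trajectory construction

Events are grouped by calendar day (the horizon h is one day, 00:00:00 to
23:59:59; daylight-saving discontinuities are taken as-is).  Events map to
cells through the sensor placement; consecutive same-cell events collapse to
one path point that keeps the first timestamp and accumulates the event
count.  Occupancy is piecewise constant between points, with the first point
extended back to midnight and the last to the end of the day, so dwell times
tile exactly 86,400 s.

Where consecutive observations are not 8-adjacent, intermediate cells are
imputed greedily: from the current cell, insert the traversable neighbor x
minimizing d(current, x) + d(x, goal) (Euclidean between cell centers, in
grid units — the physical cell size cancels).  Ties prefer the candidate
closer to the goal, then smaller row, then smaller column.  On convex
(obstacle-free) geometry this reproduces the shortest 8-connected path; a
breadth-first-search fallback covers concave obstacles where the greedy rule
would revisit a cell.

Imputed points carry timestamps that place the walk *just before* the next
observation at a nominal pace of 3 s per cell (evenly spread when the gap is
shorter).  The alternative — linear interpolation across the whole gap —
attributes large parts of long dwells to transit cells whenever an area's
last sensor event precedes the departure, which measurably distorts the
duration features; keeping dwell with the last observed cell matches how
people actually occupy space between sensor firings.

## The 14 features

Each day τ yields ϕ_τ with ten duration features and four activity features,
in fixed order (`d_toilet, d_bathroom_sink, d_livingroom_chair,
d_kitchen_sink, d_bedroom, d_kitchen, d_livingroom, d_hallway, d_stove,
d_office_chair, o_toilet, o_livingroom_chair, o_kitchen_sink,
o_office_chair`):

* `d_area` — seconds dwelt in cells labeled with that area / 86,400.
* `o_area` — (non-STAY steps originating in the area + sensor events
  observed there) / the day's total of such steps and events over all cells.

Both families are bounded in [0, 1] and comparable across homes with
different sensor counts.  Cell labels are **disjoint** by default, so the
base duration features sum to at most 1 and each area's preference weight is
separately identifiable.  An optional parent map (`NESTED_PARENTS`) lets
dwell at a nested fixture (kitchen sink, stove, living-room chair) also
accrue to the enclosing room; note that overlapping features introduce
directions of θ along which the likelihood is flat (adding c to a room
weight and subtracting it from its fixtures changes nothing observable), so
recovery experiments use the disjoint convention.

Per-step attribution is the primitive: each trajectory step carries its
dwell increment /86,400 and activity increment / day total, so summing steps
at γ = 1 reproduces the per-day vector exactly and discounted sums give the
feature expectations μ (Eq.-style: μ = E[Σᵢ γⁱ ϕ(sᵢ,aᵢ)]).  The default
γ = 1 is well-defined because the horizon is finite (one day).

Feature values from real sensing are *measurements*, not ground truth: an
area's dwell is only observed from its first to its last sensor event, so at
sparse event rates the residual dwell after the last event is attributed to
the departure walk.  The end-to-end consistency test verifies that parsed
and ground-truth features agree in the dense-event regime.

## Relative-entropy IRL

Among trajectory distributions P, the method selects the one minimizing
KL(P‖Q) to a preference-free baseline Q subject to
|E_P[ϕᵢ] − μᵢ| ≤ εᵢ.  The solution is the exponential tilt
P(τ|θ) ∝ Q(τ)·exp(θ·ϕ_τ), and θ maximizes the Lagrange dual

    g(θ) = θ·μ − ln Z(θ) − Σᵢ εᵢ|θᵢ|,
    ∂g/∂θᵢ = μᵢ − E_{P(·|θ)}[ϕᵢ] − σᵢεᵢ,  σᵢ = sign(θᵢ) (+1 at 0).

### Constraint slack ε

The default εᵢ is an empirical-Bernstein-style bound,
σ̂ᵢ·sqrt(2·ln(3k/δ)/n) at δ = 0.05, using each feature's observed per-day
standard deviation (unit-range fallback when a feature never varies).  The
classical range-based Hoeffding form εᵢ = rangeᵢ·sqrt(ln(2k/δ)/(2n)) is
available (`epsilon="hoeffding"`); with the a-priori range 1 it yields
ε ≈ 0.23 at n = 60 days, an L1 penalty strong enough to zero out all but the
one or two largest features, which destroys the vector-level comparisons the
package exists for.  The sd-scaled form keeps the constraints informative at
realistic day counts.

### Evaluating Z(θ): why a closed-form routine baseline

Three evaluation modes are provided (`IrlConfig.sample_mode`):

* **`"routine"` (default).**  Z(θ) in closed form under an analytic
  preference-free *routine* baseline: a day is `visits_per_day` independent
  visits, each targeting one of the ten areas uniformly, dwelling the
  typical duration m̄, and emitting Poisson sensor events at rate r while
  there (plus a constant per-visit move count).  The per-visit log-MGF of
  the feature increment is

      g_c(θ) = s_c·m̄/86400 + r·m̄·(exp(t_c/M) − 1) + t_c·mpv/M,

  with s and t the duration/activity weights of area c, M the typical daily
  activity total and mpv the per-visit move count; ln Z = n_v·ln Σ_c q_c·e^{g_c}.
  The tilted visit distribution is a softmax of g, so any observed
  composition — including strong suppression of rarely visited areas — is
  matched at finite θ, and the gradient is exact, smooth and free of
  sampling noise.  m̄, n_v, r, M and mpv are calibrated from the observed
  trajectories (visits counted as entries into labeled areas).  Occupancy
  and activity from brief pass-throughs (dwell < 120 s) express route
  geometry rather than dwelling preference and enter the baseline as a
  constant offset.

* **`"rollout"`.**  Self-normalized importance sampling over fresh rollouts
  of the uniform baseline policy on the MDP.  Implemented faithfully, but at
  realistic day lengths (hundreds to thousands of steps) the rollout feature
  cloud cannot reach the observed feature expectations (a resident's day is
  astronomically unlikely under a random walk), so the dual diverges along
  the dominant features — the known support-mismatch pathology of
  trajectory-level importance sampling.

* **`"observed"`.**  A subset of the observed days as the sample set, with
  the sampling policy π̂ estimated by add-1 per-cell action frequencies.
  Also faithful, but log Q − log π̂ over thousands of steps spans hundreds of
  nats, so the self-normalized weights degenerate to a point mass (flagged
  by an effective-sample-size warning).

The baseline measure Q over trajectories factors as Stran·Atran with a
per-state action distribution that is uniform over the *valid* moves (STAY
plus traversable neighbors); this keeps per-state probabilities summing to 1
and makes rollouts exact draws from Q.

### Fitting

`fit` runs gradient ascent from a small seeded random initialization with a
per-feature learning rate (default 1.0 in routine mode, 0.05 in the sampled
modes), stopping when every |∂g/∂θᵢ| ≤ εᵢ or after `max_iter = 2000`
iterations.  Routine mode uses proximal steps — a gradient step on the
smooth part followed by the exact soft-threshold of the L1 term, with
backtracking so the dual trace is non-decreasing — because plain subgradient
steps oscillate at the |θ| kink for features with no observed variation.
The stopping rule uses the min-norm generalized gradient (coordinates
resting at 0 contribute the ε-shrunk mismatch).

Two deliberate regularization properties are worth knowing about.  First,
at the exact dual optimum the ε-L1 penalty interacts with the softmax
coupling of the routine baseline to produce sparse solutions (suppressing a
few areas re-normalizes the rest into agreement), which erases rank
information across features; the default iteration budget stops ascent
before that collapse, acting as early-stopping regularization.  Second,
because ε shrinks like 1/√n, fits on more days are slightly less shrunk;
recovery accuracy therefore saturates once the statistical error falls
below the model-mismatch floor (around 30 days under the default simulation
conditions).

## The synthetic-resident generator

A simulated day is a sequence of visits: a destination area is drawn with
probability ∝ schedule(hour, area)·exp(θ*_d(area)/temperature), the resident
walks there cell by cell (2 s per cell, greedy shortest steps), and dwells
for an Exp(30 min) duration.  Motion sensors fire on entry to any sensed
cell; during a dwell the area's sensor fires at `event_rate` (default
0.3/min) scaled for the four activity areas by the mean-normalized
exp(θ*_o/temperature).  The softmax-visit mechanism was chosen over a
myopic per-step action softmax deliberately: a myopic low-temperature walker
absorbs into the single best cell and never expresses the rest of θ*, so
nothing would be identifiable.  Temperature (default 0.1) is the sharpness
of preference expression; the hourly schedule (bedroom mass at night for the
cohort profiles) adds diurnal realism independent of θ*, so recovery
experiments use schedule-flat profiles.

Floorplans are 8×12 open-plan grids with all ten functional areas placed as
non-overlapping rectangles (rooms 2×2, fixtures 1×1, a 1×4 hallway), a
motion sensor on every labeled cell and a sparse lattice of extra sensors on
unlabeled space — movement is observed but gaps remain for the imputation
stage to fill.

The default cohort mirrors a two-group ambient-monitoring study: four
"decline" homes (bedroom-weighted θ*, lower event rate) and four "healthy"
homes (living room/kitchen-weighted θ*, higher event rate), 60 days each — a
desk-scale stand-in for multi-year collections.

What the generator does **not** emulate: multi-resident homes, sensor
failures or missed firings, visitors, furniture changes, seasonal routine
drift, or light/temperature sensor semantics.  Passing recovery tests
demonstrate internal consistency of pipeline + estimator under the stated
movement model, not performance on real CASAS recordings.

### Identifiability and the recovery study

Duration preferences enter through a normalized visit softmax, so θ*_d is
identifiable only up to an additive constant per day composition — the
min-max normalization used for all comparisons removes exactly that
freedom under disjoint features (with nested parents it does not, which is
the second reason disjoint labels are the default).  The recovery profile
orders all 14 true weights distinctly, with the nested-fixture areas given
the smallest weights.  Recovery is scored as cosine similarity and Spearman
rank correlation between min-max normalized fitted and true vectors, at
15/30/60 days over 10 seeds; "improvement in expectation with more data" is
assessed on the sample means with a one-standard-error tie allowance, the
resolution at which 10 seeds can distinguish expectations.

## Cohort statistics

* **Within-home change** — per-feature paired t-tests between day-level θ of
  an early and a late window, paired by day index (the only reading under
  which a *paired* test is well-defined).  Day-level fits pool the home's
  day-to-day feature variability for their ε (one day cannot calibrate its
  own slack).
* **Within-group / between-group ANOVA** — per-feature one-way ANOVA over
  month-level θ (30 consecutive days from the home's first day; incomplete
  trailing windows dropped), with homes or diagnosis labels as groups.
  Degenerate inputs (identical groups) report F = 0, p = 1.
* **Classification** — leave-one-out random forest, 100 trees, entropy
  splits, cognitive decline as the positive class; importances are mean
  impurity-decrease shares renormalized to 1.  The default leaves one
  month-sample out; `by_home=True` leaves whole homes out, avoiding
  home-identity leakage (documented trade-off: far fewer folds).
* No multiple-testing correction by default (per-feature 0.05 flags); a
  Benjamini–Hochberg option is available.

Raw (unnormalized) θ vectors are used for all tests; min-max normalization
is a reporting convention.

## Known limitations

* The routine baseline is a model; where real behavior violates the
  independent-visit structure (long correlated activity bouts, visitors),
  the fitted θ absorbs the mismatch.
* Trajectory-level importance sampling (the `rollout`/`observed` modes)
  degenerates at realistic day lengths; they are retained for methodological
  completeness and small-scale studies.
* Multi-resident homes are out of scope; the event stream is assumed to be
  one person.
* Area-level "MA" whole-room sensors are handled by assigning each a
  representative cell in the floorplan config; area-weighted mappings are
  unexplored.
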