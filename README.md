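# residentirl

Behavioral preference learning from ambient smart-home sensor streams via
relative-entropy inverse reinforcement learning.

## The problem

Homes instrumented with passive infrared motion sensors (the CASAS platform
and its relatives) produce a continuous log of timestamped events — one line
per sensor firing — as a resident moves through their day.  For researchers
in digital health, those navigation patterns are a behavioral biomarker:
changes in how much time an older adult spends in the bedroom, how active
they are near the toilet, or how their routine drifts month to month carry
signal about cognitive health.

`residentirl` turns raw event logs into interpretable **preference vectors**
and compares them across time, residents, and diagnosis groups:

1. **Floorplan MDP.** The home is quantized into a grid of cells; each state
   is a (cell, time-slot) pair and the resident chooses among 9 actions —
   stay, or move to one of the 8 adjacent cells.  Gaps between sparsely
   placed sensors are filled by a minimum-summed-Euclidean-distance
   imputation rule, so each calendar day becomes one connected trajectory τ.
2. **Features.** Every day is summarized by 14 features ϕ_τ: the fraction of
   the day dwelt in ten functional areas (`d_toilet`, `d_bedroom`,
   `d_kitchen`, ...) and the share of movement/sensor activity at four of
   them (`o_toilet`, `o_livingroom_chair`, `o_kitchen_sink`,
   `o_office_chair`).
3. **Relative-entropy IRL.** Assuming a linear reward R(s,a) = θ·ϕ(s,a), the
   method finds the trajectory distribution closest in KL divergence to a
   preference-free baseline Q subject to matching the observed feature
   expectations μ within a concentration-bound slack ε:

   P(τ|θ) = Q(τ)·exp(θ·ϕ_τ)/Z(θ),  and θ maximizes
   g(θ) = θ·μ − ln Z(θ) − Σᵢ εᵢ|θᵢ| by gradient ascent.

   The learned θ is the resident's behavioral fingerprint.
4. **Cohort statistics.** Paired t-tests quantify within-home change over
   time; one-way ANOVAs compare residents within and between diagnosis
   groups; a leave-one-out random forest (100 trees, entropy splits)
   predicts the diagnosis label from month-level θ samples.

A fully seeded synthetic-resident generator (floorplans, schedules,
preference-driven movement, Poisson sensor events) makes every stage
testable end to end against known ground truth.

## Worked example

`examples/01_simulate_and_fit.py` simulates 30 days from a known preference
vector and recovers it:

```
simulated 17296 sensor events over 30 days
built 30 daily trajectories

feature               fitted    true
d_toilet               0.490   0.596
d_bathroom_sink        0.138   0.293
...
d_bedroom              1.000   1.000
d_kitchen              0.618   0.798
d_livingroom           0.690   0.899
...

cosine similarity 0.963, Spearman rho 0.903
```

Both columns are min-max normalized preference weights; the fitted column is
learned from the sensor stream alone, and its agreement with the truth
column (cosine 0.96, rank correlation 0.90) is the package's flagship
recovery property.  `examples/02–04` walk through group comparison,
diagnosis classification and within-home change detection.

There is also a thin CLI:

```bash
residentirl simulate --out cohort/ --homes 8 --days 60 --seed 0
residentirl fit --events cohort/decline_1.log \
                --floorplan cohort/decline_1.floorplan.yaml --out fit/
residentirl compare --data cohort/ --mode group --out reports/
residentirl classify --data cohort/ --out reports/
```

## Layout

```
src/residentirl/
  sensor_io.py     event-log and floorplan I/O with validation
  gridworld.py     floorplan MDP: states, 9 actions, empirical dynamics
  trajectories.py  daily segmentation, cell paths, imputation
  features.py      the 14-feature vector, expectations, normalization
  relent_irl.py    the IRL core: dual, gradients, baselines, fitting
  simulate.py      synthetic residents with known preferences
  cohort_stats.py  t-tests, ANOVAs, leave-one-out classification
  cli.py           thin click CLI over the library
docs/methods.md    the model, assumptions, parameters and limitations
examples/          one narrative script per capability
```
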