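# Methods

## Model

`celswarm` simulates a fixed population P of N rectangular self-propelled
agents on a continuous W x H torus with a synchronized discrete clock.  Each
agent p = (l, v, a, h, w, r) carries a position l, velocity v, acceleration
a, a body rectangle of height h (along the heading) and width w (across it),
and a metric sensing radius r.  Agents perceive only *retinal* quantities:
for every neighbor n with ‖l_n − l_o‖ < r that is not fully hidden behind
nearer neighbors, the focal agent o observes

γ_n = (ψ, ψ̇, θ, θ̇),

where ψ is the angle subtended by the neighbor's body rectangle (the widest
angle between any two corner direction vectors in the focal frame), θ =
arccos( v̂_o · (l_n − l_o) / ‖l_n − l_o‖ ) the unsigned bearing off the
focal heading, and the dots are one-step backward differences.  Because θ
comes from an arccos, agents cannot distinguish left from right; the
`signed_theta` flag restores the sign as an explicitly flagged deviation
from the reference model.

Per tick, every agent (in a random order, all reading the tick-start
snapshot) chooses a heading action from a set of n = 360°/Δ discrete unit
directions (Δ = 15° by default, n = 24) and moves:

a(t+1) = x(t),  v(t+1) = v(t) + δ a(t+1),  l(t+1) = l(t) + v(t+1)  (mod W, H).

After the velocity update, v is rescaled to its pre-update magnitude, so the
action steers the heading only, in the spirit of constant-speed
self-propelled-particle models; taking the raw update instead
(`raw_velocity_update: true`) lets the speed grow without bound (each tick
can add up to δ), which destroys the slow-speed regime the defaults are
calibrated for.  A stopped agent (speed 0) restarts at speed δ along the
steered direction — the raw update applied at zero speed — so collisions
pause rather than permanently freeze an agent.

A pair collides when their predicted post-move centers are close:

‖l₁ + v₁ − l₂ − v₂‖ ≤ max(h₁ + h₂, w₁ + w₂)/2,

minimal-image on the torus.  In a head-tail collision the rammer (the agent
whose front half-plane contains the partner) is *active* and stopped for the
tick; the rammed partner is *passive* and gains the active partner's
velocity at collision time.  Frontal collisions (both fronts facing) stop
both; mutual rear contact is degenerate and treated as frontal.
Simultaneous collisions are resolved in ascending id-pair order against a
pre-resolution velocity snapshot, so the outcome is deterministic and
independent of discovery order.

## Metrics

Collective motion is measured by the scaled circular heading variance

F(P) = (1/2π) · mean_p wrap(φ_p − φ̄)²,

with φ̄ the circular-mean heading and deviations wrapped to (−π, π].  The
printed definition of this statistic is ambiguous (a squared difference of
"velocities" with a 1/2π prefactor); the angular reading is the only one in
which the complement score 1 − F spans a meaningful range at the model's
speeds (~0.1 m/s): raw velocity-vector deviations would give F ~ 10⁻³ and
score ≈ 1 for every policy.  Two finite-size facts matter when interpreting
scores: for isotropic headings E[F] → (1/2π)(π²/3) ≈ 0.524 as N → ∞, but at
N = 30 the data-dependent circular mean absorbs part of the dispersion and
the stationary value is ≈ 0.42 (score ≈ 0.58).  Both values are computed by
the test suite.

Collision avoidance is the normalized per-tick collision rate C = (colliding
pairs) / ⌊N/2⌋, the denominator being the largest possible number of
simultaneous (disjoint) colliding pairs; the all-pairs normalizer N(N−1)/2
would pin C near zero at these densities.  The combined objective over a
window is the time-mean of ζF_t + (1−ζ)C_t (averaged, not summed, so its
complement stays in [0, 1] regardless of run length); "scores" are
complements clipped to [0, 1].

## Learning (collective evolution)

The policy is a sparse tabular map from discretized observation vectors to
action weights.  The state key concatenates k = 8 neighbor slots (sorted by
ascending θ, ties by distance then id), each slot binning (ψ, ψ̇, θ, θ̇) at
0.01 (radians, and radians/step for the derivatives, clipped to ±π); absent
slots carry a sentinel bin outside the realizable range.  Unvisited states
behave as a uniform row over the 24 actions — observationally identical to
initializing every possible state uniformly, which is infeasible to
materialize.  The update is additive: q[s, a] += λ · score with λ = 0.1 (the
learning rate is not part of the reference parameter set; 0.1 is a standard
tabular magnitude) and score = 1 − (local objective) ∈ [0, 1].  There is no
bootstrap term; the update is exactly a score-weighted preference
accumulation.

Training scenarios are local patches: a focal agent at the origin with
m ~ U{0..k} neighbors uniform in its sensing disc, velocities drawn
component-wise U[0, 0.15] m/s with random signs.  For each scenario a
genetic algorithm searches length-η = 5 action sequences ("genes"):
population τ = 20, g = 10 generations, single-point crossover with the cut
uniform on [2, η], per-gene mutation probability drawn from
clip(N(μ=0.1, φ=0.05), 0, 1) mutating one position to a different action,
elitism keeping max(1, ⌊ι τ⌋) = 1 best gene, and selection proportional to
the L1-normalized complement scores.  Gene fitness is the local objective
of an η-step rollout in which the focal agent executes the gene and
neighbors move ballistically (constant velocity): the cheapest closed
assumption over the planning horizon; a flag lets neighbors follow the
current policy instead.  The first action of the best gene and its score
feed the Q update.  The rollout evaluator has a compiled (numba) kernel;
a pure-numpy reference path is kept and the two are asserted equal in the
tests.

Validation rolls Z_validate fresh scenarios η steps with *all* agents
following the stochastic policy and scores each by the complement of the
local objective (no collision protocol is applied on the patch; the metric
is predictive).  Performance is interpolated over a 3-dimensional state
descriptor (visible-neighbor count, nearest-slot ψ, nearest-slot θ, all
normalized; the empty state is its own atom) with distance-weighted KNN
(y = 3), evaluated at 10,000 uniform probes.  Deficiency weights 1 − est
are L1-normalized into a sampling distribution; training stops when its
total variation distance from uniform is ≤ κ = 0.05, else the next training
block rejection-samples scenarios against that distribution (nearest-probe
acceptance).  The exact functional mapping estimated performance to a
sampling distribution is not pinned down by the reference description;
deficiency weighting is the simplest choice with the right monotonicity.

The total training budget Z_train is spread evenly over at most 10
train/validate rounds; the learning curve records validation performance
against cumulative samples and is summarized by a least-squares fit
a·ln(samples) + b with R².  Validation reuses one fixed scenario substream
across rounds (common random numbers), so successive curve points differ
only through the policy, not through scenario resampling noise.  Testing
runs full-population simulations (N = 30, T = 500) with every agent on the
learned policy and reports the mean combined score over replicates.

## Randomness and reproducibility

All randomness flows from one master seed through named substreams
(`substream(seed, name)`, a SeedSequence keyed by a CRC of the name), so
adding replicates or reordering consumers never perturbs unrelated draws.
Fixed seeds give bit-identical trajectories; the test suite asserts this.

## Problem sizes

Default experiment sizes follow the reference configuration (N = 30,
T = 500, n = 30 replicates).  The packaged learning demonstration and its
tests use a reduced budget — Z_train = 2×10⁵ scenarios, Z_validate = 10³
per round — which trains in minutes on one core.  At this scale the tabular
policy visits each fine-grained state at most a handful of times, so the
absolute improvement over the random walk is small; the checks are
therefore ordinal (trained > random, positive learning-curve slope) rather
than absolute score levels.

## What the scenario generator does and does not emulate

Generated patches reproduce the geometry (disc-uniform neighbors within r,
body dimensions, initial speed distribution) and the action discretization
of the full simulation.  They are static snapshots: every neighbor is seen
for the first time, so observation derivatives are zero, whereas in a
running swarm persistent neighbors carry nonzero ψ̇, θ̇.  Trained states
therefore concentrate on the zero-derivative slice of the state space, and
transfer to a running swarm happens mainly through slowly-changing (nearly
aligned) configurations.  Passing the learning tests shows the pipeline
optimizes what it measures; it does not show that the reduced-scale policy
is a competent flocker.

## Numerical choices

* Bins are half-open with a floor rule; a 1e-9 relative nudge guards
  against representation error at bin edges (0.1049/0.01 → bin 10).
* The sentinel bin is ⌊π/bin⌋ + 2, above any realizable angle or clipped
  derivative bin for the configured width.
* arccos arguments are clipped to [−1, 1]; a focal center inside a
  neighbor's body yields ψ = π with a warning.
* Zero-speed agents keep their last nonzero heading for corner geometry,
  bearings and the CM metric; an agent with no heading history defaults to
  +x (flagged in logs).
* Greedy action selection breaks ties toward the lowest index; occlusion
  ordering breaks distance ties by id.
* Score clipping to [0, 1] guards the (unreachable in practice) F > 1 edge.

## Known limitations

* The tabular policy cannot generalize across bins; at 0.01-rad resolution
  the reachable state space dwarfs any practical training budget, so
  multi-neighbor states are effectively always novel.  A coarser bin width
  or a function approximator would trade fidelity to the reference design
  for sample efficiency.
* The unsigned θ makes left and right indistinguishable, so learned
  avoidance cannot be chiral.
* Planner rollouts assume ballistic neighbors; in dense patches this
  overestimates collision risk for neighbors that would themselves swerve.
* The collision disc max(h₁+h₂, w₁+w₂)/2 is generous for elongated bodies:
  side-by-side agents register collisions without physical overlap.
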