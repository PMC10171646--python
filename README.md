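# celswarm

Vision-based collective motion with collision avoidance: an agent-based
swarm simulator and a collective-evolution learning (CEL) pipeline, built
for studying how group-level flocking can emerge from individual-level
learning in animals such as marching locusts.

## The problem

Classic self-propelled-particle models of flocking assume each agent knows
its neighbors' exact positions and velocities.  Real animals do not: they
see.  `celswarm` models N rectangular agents (body height h along the
heading, width w across it — locust-like at h/w = 7) on a W x H toroidal
arena whose only sensory input is retinal: for every neighbor inside the
sensing radius r that is not fully hidden behind nearer neighbors, an agent
observes

γ = (ψ, ψ̇, θ, θ̇)

— the subtended angle ψ of the neighbor's body on its retina, the unsigned
angular position θ of the neighbor off its own heading, and their one-step
time differences.  Each tick every agent picks one of n = 360°/Δ discrete
heading actions (Δ = 15°); the velocity update v ← v + δa is renormalized
to constant speed, positions wrap on the torus, and a predictive collision
rule stops the "active" (ramming) collider for a tick while the passive one
receives its partner's velocity.

Swarm performance combines two order parameters: the collective-motion
metric F (scaled circular variance of headings, 0 = perfectly aligned) and
the collision-avoidance metric C (colliding pairs per tick over the maximum
possible ⌊N/2⌋).  Policies minimize the time-mean of ζF_t + (1−ζ)C_t;
reported *scores* are complements (1 = aligned and collision-free).

Learning proceeds without gradients and without a global teacher: for each
randomly generated local scenario (a focal agent with up to k neighbors), a
genetic algorithm plans the best η-step action sequence against the local
objective, and the first action's score updates a sparse tabular stochastic
policy (q[s, a] += λ·score).  A KNN-interpolated performance map over the
state space redirects scenario sampling toward poorly learned regions, with
a total-variation-distance stop rule.  Details, parameter meanings and
design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from celswarm import RunConfig, run_simulation, substream
from celswarm.qpolicy import RandomWalkPolicy
from celswarm.metrics import cmca_score

cfg = RunConfig()                       # 30 agents, 5x5 m torus, 500 ticks
policy = RandomWalkPolicy(cfg.n_actions)
state = run_simulation(cfg, policy, substream(seed=1, name="demo"))
s = state.series
print(f"final CM score   {s.cm_score[-1]:.3f}")
print(f"final CA score   {s.ca_score[-1]:.3f}")
print(f"mean CMCA score  {cmca_score(s):.3f}")
print(f"collisions       {len(state.collision_log)}")
```

prints

```
final CM score   0.668
final CA score   1.000
mean CMCA score  0.784
collisions       166
```

Under the uniform random-walk policy headings diffuse to isotropy, so the
CM score settles near its finite-population stationary level (≈ 0.58 on
average over replicates; this single run ends a bit above it), while at the
default density collisions are rare events (166 over 30 agents x 500 ticks
≈ 0.33 per tick), so the per-tick CA score stays near 1.

The same run is available from the shell, along with training, testing and
the canned experiments (baseline comparison, population/aspect-ratio/radius
sweeps, random-forest policy surrogates):

```bash
cel simulate --policy random --steps 500 --reps 1 --seed 7 --out out/
cel train --config cfg.yaml --out policy.qz
cel test  --policy policy.qz --reps 30 --out scores.csv
cel experiment --name baselines --policy policy.qz --reps 30 --out exp/
```

Every command writes a `manifest.json` (config, seed, versions) beside its
outputs, and all randomness flows from the seed through named substreams,
so reruns are bit-identical.

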