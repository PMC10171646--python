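"""Synchronous discrete-time world dynamics and the collision protocol.

Each tick: (1) every agent senses the tick-start snapshot and chooses an
action (a desired heading from the discretized action set), in a random
order; (2) every agent moves — the action becomes its acceleration, the
velocity is steered toward it with weight δ and rescaled to its pre-update
speed, and the position advances with toroidal wrapping; (3) collisions are
detected with the predictive center-distance condition and resolved: active
colliders (the ones whose front faces the partner) are stopped for the tick,
passive colliders gain the partner's velocity.

Speed renormalization makes actions pure heading changes; taking the raw
velocity update instead (``raw_velocity_update``) lets speed drift without
bound, destroying the slow-speed regime the model is calibrated in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import ScoreSeries, ca_from_pair_count, cm_metric
from .vision import AgentState, EnvironmentConfig, encode_state, minimal_image, perceive

logger = logging.getLogger(__name__)

__all__ = ["Action", "CollisionEvent", "SimulationState", "action_directions",
           "apply_action", "wrap_position", "detect_collisions",
           "classify_roles", "resolve_collision", "step_world",
           "init_world", "run_simulation"]


@dataclass(frozen=True)
class Action:
    """Discrete heading action: unit direction at index·Δ degrees from +x."""
    index: int
    direction: np.ndarray


def action_directions(n_actions: int) -> np.ndarray:
    """(n, 2) unit vectors of the discretized action set."""
    ang = np.arange(n_actions) * (2 * np.pi / n_actions)
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def make_action(index: int, n_actions: int) -> Action:
    return Action(index=int(index), direction=action_directions(n_actions)[int(index)])


@dataclass(frozen=True)
class CollisionEvent:
    agent_ids: tuple[int, int]
    roles: tuple[str, str]      # each "active" or "passive"
    time: int = 0


def wrap_position(l: np.ndarray, env: EnvironmentConfig) -> np.ndarray:
    """Map a position into [0, W) x [0, H)."""
    return np.array([l[0] % env.width, l[1] % env.height])


def apply_action(agent: AgentState, action: Action, delta: float,
                 env: Optional[EnvironmentConfig] = None,
                 raw: bool = False) -> AgentState:
    """Advance one agent: a ← action direction; v ← v + δa (rescaled to the
    pre-update speed unless ``raw``); l ← l + v, wrapped.

    A stopped agent (speed 0) restarts at speed δ in the steered direction.
    Mutates and returns the agent.
    """
    agent.a = np.asarray(action.direction, dtype=float)
    v_new = agent.v + delta * agent.a
    if not raw:
        speed0 = agent.speed
        s_new = float(np.hypot(*v_new))
        if speed0 > 0:
            v_new = v_new * (speed0 / s_new) if s_new > 0 else np.zeros(2)
        # speed0 == 0: restart at |v| = δ along the action direction
    agent.v = v_new
    if float(np.hypot(*v_new)) > 0:
        agent.last_heading = v_new / float(np.hypot(*v_new))
    agent.l = agent.l + agent.v
    if env is not None:
        agent.l = wrap_position(agent.l, env)
    return agent


def _pair_threshold(a1: AgentState, a2: AgentState) -> float:
    return max(a1.h + a2.h, a1.w + a2.w) / 2.0


def detect_collisions(agents: Sequence[AgentState],
                      env: Optional[EnvironmentConfig] = None,
                      predictive: bool = True, time: int = 0) -> list[CollisionEvent]:
    """Colliding pairs: minimal-image distance between the agents' post-move
    centers (l + v when ``predictive``, else current l) at most
    max(h1+h2, w1+w2)/2.  Roles are assigned by :func:`classify_roles`."""
    n = len(agents)
    if n < 2:
        return []
    pos = np.array([a.l + a.v if predictive else a.l for a in agents])
    hs = np.array([a.h for a in agents])
    ws = np.array([a.w for a in agents])
    iu, ju = np.triu_indices(n, k=1)
    disp = minimal_image(pos[ju] - pos[iu], env)
    d = np.hypot(disp[:, 0], disp[:, 1])
    thr = np.maximum(hs[iu] + hs[ju], ws[iu] + ws[ju]) / 2.0
    events = []
    for k in np.nonzero(d <= thr)[0]:
        i, j = int(iu[k]), int(ju[k])
        roles = classify_roles(agents[i], agents[j], env)
        events.append(CollisionEvent(agent_ids=(agents[i].id, agents[j].id),
                                     roles=roles, time=time))
    return events


def classify_roles(a1: AgentState, a2: AgentState,
                   env: Optional[EnvironmentConfig] = None) -> tuple[str, str]:
    """Active iff the partner's center lies in the agent's front half-plane.
    Both facing each other → frontal, both active; mutual rear contact is
    degenerate and treated as both active."""
    disp = minimal_image(a2.l - a1.l, env)
    front1 = float(a1.heading @ disp) > 0
    front2 = float(a2.heading @ (-disp)) > 0
    if front1 and not front2:
        return ("active", "passive")
    if front2 and not front1:
        return ("passive", "active")
    if not front1 and not front2:
        logger.debug("degenerate mutual rear contact between %s and %s", a1.id, a2.id)
    return ("active", "active")


def resolve_collision(events: Sequence[CollisionEvent],
                      agents: Sequence[AgentState]) -> list[AgentState]:
    """Apply the collision protocol for all events of one tick.

    Events are processed in ascending (id, id) order; each active agent's
    velocity is zeroed for the tick, each passive agent gains its partner's
    velocity *at collision time* (the pre-resolution snapshot), so multiple
    simultaneous collisions compose deterministically.
    """
    by_id = {a.id: a for a in agents}
    snapshot = {a.id: a.v.copy() for a in agents}
    for ev in sorted(events, key=lambda e: tuple(sorted(e.agent_ids))):
        (i, j) = ev.agent_ids
        for me, other, role in ((i, j, ev.roles[0]), (j, i, ev.roles[1])):
            if role == "active":
                by_id[me].v = np.zeros(2)
            else:
                by_id[me].v = by_id[me].v + snapshot[other]
    return list(agents)


class Policy:
    """Minimal policy interface: maps an encoded state to an action index."""
    state_independent: bool = False
    n_actions: int = 24

    def select(self, state, rng: np.random.Generator) -> int:  # pragma: no cover
        raise NotImplementedError


@dataclass
class SimulationState:
    """Full-world simulation: tick counter, agents, score accumulator and the
    per-agent previous observations used for temporal derivatives."""
    env: EnvironmentConfig
    agents: list[AgentState]
    t: int = 0
    series: ScoreSeries = field(default_factory=ScoreSeries)
    prev_obs: dict = field(default_factory=dict)
    collision_log: list = field(default_factory=list)
    trajectory: list = field(default_factory=list)
    record_trajectory: bool = False
    max_neighbors: int = 8
    state_bin: float = 0.01
    delta: float = 0.05
    signed_theta: bool = False
    raw_velocity_update: bool = False

    def record_metrics(self, events: Sequence[CollisionEvent]) -> None:
        f = cm_metric(self.agents)
        c = ca_from_pair_count(len(events), len(self.agents))
        self.series.record(f, c)
        if self.record_trajectory:
            collided = {i for ev in events for i in ev.agent_ids}
            for a in self.agents:
                self.trajectory.append((self.t, a.id, a.l[0], a.l[1],
                                        a.v[0], a.v[1], int(a.id in collided)))

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory,
                            columns=["t", "id", "lx", "ly", "vx", "vy", "collided"])

    def write_collision_log(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.collision_log:
                fh.write(json.dumps({"t": ev.time, "ids": list(ev.agent_ids),
                                     "roles": list(ev.roles)}) + "\n")


def init_world(cfg, rng: np.random.Generator,
               record_trajectory: bool = False) -> SimulationState:
    """Random initial condition: positions uniform in the arena, initial
    velocity components each U[0, v_init_max] (the reference configuration's
    initial distribution), zero acceleration."""
    env = EnvironmentConfig(width=cfg.width, height=cfg.height)
    agents = []
    for i in range(cfg.population_size):
        l = np.array([rng.uniform(0, cfg.width), rng.uniform(0, cfg.height)])
        v = rng.uniform(0.0, cfg.v_init_max, size=2)
        agents.append(AgentState(id=i, l=l, v=v, h=cfg.body_height,
                                 w=cfg.body_width, r=cfg.sensing_radius))
    state = SimulationState(
        env=env, agents=agents, series=ScoreSeries(zeta=cfg.zeta),
        record_trajectory=record_trajectory, max_neighbors=cfg.max_neighbors,
        state_bin=cfg.state_bin, delta=cfg.delta, signed_theta=cfg.signed_theta,
        raw_velocity_update=cfg.raw_velocity_update)
    state.record_metrics(detect_collisions(agents, env, time=0))
    return state


def _snapshot(agents: Sequence[AgentState]) -> list[AgentState]:
    return [AgentState(id=a.id, l=a.l.copy(), v=a.v.copy(), a=a.a.copy(),
                       h=a.h, w=a.w, r=a.r,
                       last_heading=None if a.last_heading is None
                       else a.last_heading.copy())
            for a in agents]


def step_world(state: SimulationState, policy: Policy,
               rng: np.random.Generator) -> SimulationState:
    """Advance the world by one tick (sense → act → move → collide)."""
    agents = state.agents
    n = len(agents)
    dirs = action_directions(policy.n_actions)
    if policy.state_independent:
        # no sensing needed; the action order permutation is still drawn so
        # RNG consumption matches the general path
        order = rng.permutation(n)
        chosen = np.empty(n, dtype=int)
        for i in order:
            chosen[i] = policy.select(None, rng)
    else:
        snap = _snapshot(agents)
        pos = np.array([a.l for a in snap])
        new_prev: dict = {}
        chosen = np.empty(n, dtype=int)
        for i in rng.permutation(n):
            focal = snap[i]
            disp = minimal_image(pos - focal.l[None, :], state.env)
            d = np.hypot(disp[:, 0], disp[:, 1])
            idx = [j for j in np.nonzero(d < focal.r)[0] if j != i]
            obs = perceive(focal, [snap[j] for j in idx],
                           previous_observation=state.prev_obs.get(focal.id),
                           env=state.env, signed_theta=state.signed_theta)
            new_prev[focal.id] = {o.neighbor_id: o for o in obs}
            enc = encode_state(obs, state.max_neighbors, state.state_bin)
            chosen[i] = policy.select(enc, rng)
        state.prev_obs = new_prev
    for i, a in enumerate(agents):
        apply_action(a, Action(index=int(chosen[i]), direction=dirs[chosen[i]]),
                     state.delta, state.env, raw=state.raw_velocity_update)
    state.t += 1
    # post-move contact: current centers, the predictive condition applied at
    # move time
    events = detect_collisions(agents, state.env, predictive=False, time=state.t)
    resolve_collision(events, agents)
    state.collision_log.extend(events)
    state.record_metrics(events)
    return state


def run_simulation(cfg, policy: Policy, rng: np.random.Generator,
                   n_steps: Optional[int] = None,
                   record_trajectory: bool = False) -> SimulationState:
    """Run a full simulation of T ticks from a random initial condition."""
    state = init_world(cfg, rng, record_trajectory=record_trajectory)
    for _ in range(n_steps if n_steps is not None else cfg.n_steps):
        step_world(state, policy, rng)
    return state
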