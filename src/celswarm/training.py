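"""Collective evolution learning: the train / validate / test loop.

Training repeatedly (i) draws a random local scenario — a focal agent with
up to k neighbors inside its sensing radius on an unbounded patch, (ii) asks
the GA planner for the best first action and its score, and (iii) adds
λ·score to the Q-table entry of the encoded state and chosen action.

Validation rolls random scenarios forward with *all* agents following the
Q-policy, scores each rollout by the complement of the local CMCA objective,
and interpolates this performance over a uniform probe of the state-
descriptor space with distance-weighted KNN.  Where estimated performance is
poor, probability mass is placed for the next round's scenario sampling
(rejection sampling); when the deficiency distribution is within total
variation distance κ of uniform, training stops.

Testing runs full-population simulations with every agent on the learned
policy and reports the mean CMCA score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.neighbors import KNeighborsRegressor

from .config import RunConfig, substream
from .dynamics import Action, action_directions, apply_action, run_simulation
from .ga import GAConfig, plan
from .metrics import cmca_score, local_objective
from .qpolicy import QTable, QTablePolicy
from .vision import AgentState, encode_state, perceive

logger = logging.getLogger(__name__)

__all__ = ["Scenario", "SamplingDistribution", "generate_scenario",
           "train_phase", "validate_phase", "test_phase", "fit_and_test",
           "fit_log_curve", "TrainReport"]


@dataclass
class Scenario:
    """A local training/validation patch: focal agent at the origin plus up
    to k neighbors within its sensing radius (no wrapping during rollouts)."""
    focal: AgentState
    neighbors: list[AgentState]
    _obs_cache: Optional[list] = field(default=None, repr=False, compare=False)

    def observations(self, cfg: RunConfig, previous=None):
        """Initial observations of the (static) patch; cached, since the
        scenario is immutable until a rollout copies its agents."""
        if previous is not None:
            return perceive(self.focal, self.neighbors,
                            previous_observation=previous,
                            signed_theta=cfg.signed_theta)
        if self._obs_cache is None:
            self._obs_cache = perceive(self.focal, self.neighbors,
                                       signed_theta=cfg.signed_theta)
        return self._obs_cache

    def encoded_state(self, cfg: RunConfig):
        return encode_state(self.observations(cfg), cfg.max_neighbors, cfg.state_bin)


def _descriptor(observations, cfg: RunConfig) -> np.ndarray:
    """Normalized state descriptor (visible count / k, nearest ψ/π, nearest
    θ/π); the empty ("alone") state maps to a separate point below the
    occupied range."""
    if not observations:
        return np.array([0.0, -0.1, -0.1])
    nearest = min(observations, key=lambda o: o.distance)
    return np.array([len(observations) / cfg.max_neighbors,
                     nearest.psi / math.pi, abs(nearest.theta) / math.pi])


@dataclass
class SamplingDistribution:
    """Probability weights over probe points of the state-descriptor space,
    used to bias scenario generation toward poorly learned regions."""
    probes: np.ndarray            # (n, 3) normalized descriptors
    weights: np.ndarray           # (n,) nonnegative, sums to 1
    _tree: Optional[cKDTree] = field(default=None, repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("weights must be nonnegative and sum to 1")
        self.weights = w
        self._tree = cKDTree(self.probes)

    def tvd_from_uniform(self) -> float:
        n = len(self.weights)
        return float(0.5 * np.abs(self.weights - 1.0 / n).sum())

    def acceptance_probability(self, descriptor: np.ndarray) -> float:
        _, idx = self._tree.query(descriptor)
        wmax = self.weights.max()
        return float(self.weights[idx] / wmax) if wmax > 0 else 1.0


def _random_velocity(cfg: RunConfig, rng: np.random.Generator) -> np.ndarray:
    """Component-wise U[0, v_init_max] magnitudes with random signs."""
    return rng.uniform(0.0, cfg.v_init_max, 2) * rng.choice([-1.0, 1.0], 2)


def generate_scenario(cfg: RunConfig, rng: np.random.Generator,
                      bias: Optional[SamplingDistribution] = None,
                      max_tries: int = 50) -> Scenario:
    """Random scenario: neighbor count uniform on [0, k], neighbor positions
    uniform in the sensing disc, velocities from the initial distribution.
    With a bias distribution, candidates are rejection-sampled so accepted
    scenarios follow the bias over the descriptor space."""
    for _ in range(max_tries):
        m = int(rng.integers(0, cfg.max_neighbors + 1))
        focal = AgentState(id=0, l=np.zeros(2), v=_random_velocity(cfg, rng),
                           h=cfg.body_height, w=cfg.body_width, r=cfg.sensing_radius)
        neighbors = []
        for j in range(m):
            rad = cfg.sensing_radius * math.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * math.pi)
            neighbors.append(AgentState(
                id=j + 1, l=rad * np.array([math.cos(ang), math.sin(ang)]),
                v=_random_velocity(cfg, rng), h=cfg.body_height,
                w=cfg.body_width, r=cfg.sensing_radius))
        sc = Scenario(focal=focal, neighbors=neighbors)
        if bias is None:
            return sc
        desc = _descriptor(sc.observations(cfg), cfg)
        if rng.random() < bias.acceptance_probability(desc):
            return sc
    return sc  # rejection cap reached; accept the last candidate


def train_phase(q: QTable, cfg: RunConfig, rng: np.random.Generator,
                bias: Optional[SamplingDistribution] = None,
                n_samples: Optional[int] = None) -> QTable:
    """One block of scenario → GA plan → Q-update iterations."""
    n = n_samples if n_samples is not None else cfg.z_train
    ga_cfg = GAConfig.from_run_config(cfg)
    for _ in range(n):
        sc = generate_scenario(cfg, rng, bias=bias)
        state = sc.encoded_state(cfg)
        action, score = plan(sc, ga_cfg, cfg.zeta, rng)
        q.update(state, action.index, score)
    return q


def _rollout_policy(sc: Scenario, policy: QTablePolicy, cfg: RunConfig,
                    rng: np.random.Generator) -> float:
    """η-step patch rollout with every agent following the policy; returns
    the performance 1 − local CMCA objective (collision metrics are recorded
    predictively; no collision protocol is applied on the patch)."""
    agents = [sc.focal] + sc.neighbors
    dirs = action_directions(policy.n_actions)
    prev: dict = {}
    snapshots = [[AgentState(id=a.id, l=a.l.copy(), v=a.v.copy(), h=a.h, w=a.w,
                             r=a.r, last_heading=a.last_heading) for a in agents]]
    for _ in range(cfg.horizon):
        chosen = []
        for a in agents:
            others = [b for b in agents
                      if b.id != a.id and float(np.hypot(*(b.l - a.l))) < a.r]
            obs = perceive(a, others, previous_observation=prev.get(a.id),
                           signed_theta=cfg.signed_theta)
            prev[a.id] = {o.neighbor_id: o for o in obs}
            enc = encode_state(obs, cfg.max_neighbors, cfg.state_bin)
            chosen.append(policy.select(enc, rng))
        for a, ai in zip(agents, chosen):
            apply_action(a, Action(index=ai, direction=dirs[ai]), cfg.delta,
                         env=None, raw=cfg.raw_velocity_update)
        snapshots.append([AgentState(id=a.id, l=a.l.copy(), v=a.v.copy(), h=a.h,
                                     w=a.w, r=a.r, last_heading=a.last_heading)
                          for a in agents])
    obj = local_objective(snapshots, cfg.zeta)
    return float(np.clip(1.0 - obj, 0.0, 1.0))


def validate_phase(q: QTable, cfg: RunConfig, rng: np.random.Generator,
                   n_scenarios: Optional[int] = None
                   ) -> tuple[float, SamplingDistribution, bool]:
    """Measure the policy, interpolate its performance over the descriptor
    space, and derive the next sampling distribution.

    Returns (mean rollout performance, deficiency-weighted sampling
    distribution over uniform probes, stop flag: TVD(distribution, uniform)
    ≤ κ).
    """
    n = n_scenarios if n_scenarios is not None else cfg.z_validate
    policy = QTablePolicy(q, mode="stochastic")
    descs, perfs = [], []
    for _ in range(n):
        sc = generate_scenario(cfg, rng)
        descs.append(_descriptor(sc.observations(cfg), cfg))
        perfs.append(_rollout_policy(sc, policy, cfg, rng))
    descs = np.asarray(descs)
    perfs = np.asarray(perfs)
    knn = KNeighborsRegressor(n_neighbors=min(cfg.knn_neighbors, len(perfs)),
                              weights="distance")
    knn.fit(descs, perfs)
    # uniform probe of the descriptor space (the alone state is its own atom)
    counts = rng.integers(0, cfg.max_neighbors + 1, size=cfg.n_probes)
    probes = np.column_stack([
        counts / cfg.max_neighbors,
        np.where(counts > 0, rng.uniform(0, 1, cfg.n_probes), -0.1),
        np.where(counts > 0, rng.uniform(0, 1, cfg.n_probes), -0.1)])
    est = np.clip(knn.predict(probes), 0.0, 1.0)
    deficiency = 1.0 - est
    total = deficiency.sum()
    if total <= 0:
        weights = np.full(len(probes), 1.0 / len(probes))
    else:
        weights = deficiency / total
    dist = SamplingDistribution(probes=probes, weights=weights)
    stop = dist.tvd_from_uniform() <= cfg.kappa
    return float(perfs.mean()), dist, stop


def test_phase(q: QTable, cfg: RunConfig, rng_seed: int, reps: int = 30,
               mode: str = "stochastic") -> tuple[float, list]:
    """Full-population simulations with every agent on the learned policy;
    returns (mean CMCA score over runs, per-run score series)."""
    policy = QTablePolicy(q, mode=mode)
    scores, series = [], []
    for rep in range(reps):
        rng = substream(rng_seed, f"test-{rep}")
        state = run_simulation(cfg, policy, rng)
        scores.append(cmca_score(state.series))
        series.append(state.series)
    return float(np.mean(scores)), series


def fit_log_curve(samples: Sequence[float], perf: Sequence[float]
                  ) -> tuple[float, float, float]:
    """Least-squares fit perf = a·ln(samples) + b; returns (a, b, R²)."""
    x = np.log(np.asarray(samples, dtype=float))
    y = np.asarray(perf, dtype=float)
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(a), float(b), r2


@dataclass
class TrainReport:
    q: QTable
    curve: pd.DataFrame                 # cumulative samples vs validation performance
    log_fit: tuple[float, float, float]  # (slope a, intercept b, R²)
    test_score: float
    test_series: list
    rounds: int


def fit_and_test(cfg: RunConfig, reps: int = 30,
                 test_mode: str = "stochastic") -> TrainReport:
    """The full loop: alternate training and validation until the sampling
    distribution is κ-close to uniform (or the round cap / sample budget is
    exhausted), then test.

    The training budget Z_train is spread evenly over the rounds; validation
    reuses a fixed substream each round (common random numbers) so the
    learning curve reflects policy improvement rather than resampling noise.
    """
    cfg.validate()
    q = QTable(n_actions=cfg.n_actions, learning_rate=cfg.learning_rate,
               bin_width=cfg.state_bin, max_neighbors=cfg.max_neighbors)
    z_round = max(1, math.ceil(cfg.z_train / cfg.max_rounds))
    rng_train = substream(cfg.seed, "train")
    bias = None
    points = []
    consumed = 0
    rounds = 0
    for rnd in range(cfg.max_rounds):
        n_block = min(z_round, cfg.z_train - consumed)
        if n_block <= 0:
            break
        train_phase(q, cfg, rng_train, bias=bias, n_samples=n_block)
        consumed += n_block
        rounds += 1
        mean_perf, dist, stop = validate_phase(
            q, cfg, substream(cfg.seed, "validate"))
        points.append((consumed, mean_perf, dist.tvd_from_uniform()))
        logger.info("round %d: %d samples, validation performance %.4f, TVD %.4f",
                    rnd, consumed, mean_perf, points[-1][2])
        if stop:
            break
        bias = dist
    curve = pd.DataFrame(points, columns=["samples", "performance", "tvd"])
    if len(curve) >= 2:
        log_fit = fit_log_curve(curve["samples"], curve["performance"])
    else:
        log_fit = (math.nan, math.nan, math.nan)
    test_score, series = test_phase(q, cfg, cfg.seed, reps=reps, mode=test_mode)
    return TrainReport(q=q, curve=curve, log_fit=log_fit, test_score=test_score,
                       test_series=series, rounds=rounds)
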