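"""Genetic-algorithm action planner for a single focal agent.

Given a local scenario (focal agent + up to k neighbors), the planner
searches over genes — length-η sequences of discrete heading actions — for
the sequence minimizing the local CMCA objective over an η-step rollout in
which the focal agent executes the gene and the neighbors move ballistically
(constant velocity).  Standard single-point crossover, single-position
mutation and elitist fitness-proportionate selection are used; the first
action of the best gene and its complement score (1 − objective) feed the
Q-table update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .dynamics import Action, action_directions, make_action
from .metrics import TWO_PI

__all__ = ["Gene", "GAConfig", "init_population", "crossover", "mutate",
           "next_generation", "plan", "evaluate_genes", "exhaustive_population"]


@dataclass
class Gene:
    """A candidate η-step action sequence and its objective value (lower is
    better)."""
    actions: np.ndarray
    fitness: float = math.nan


@dataclass
class GAConfig:
    population: int = 20          # τ
    generations: int = 10         # g
    elite_fraction: float = 0.05  # ι ("royalty rate")
    mutation_mean: float = 0.1    # μ: mean of the per-gene mutation probability
    mutation_sd: float = 0.05     # φ: its standard deviation
    horizon: int = 5              # η
    n_actions: int = 24
    delta: float = 0.05
    crossover_weights: Optional[np.ndarray] = None  # over cut points [2, η]

    def __post_init__(self):
        if self.population < 2 or self.generations < 1:
            raise ValueError("need population >= 2 and generations >= 1")

    @property
    def n_elite(self) -> int:
        return max(1, int(self.elite_fraction * self.population))

    def cut_weights(self) -> np.ndarray:
        if self.crossover_weights is not None:
            w = np.asarray(self.crossover_weights, dtype=float)
        else:
            w = np.ones(self.horizon - 1)
        return w / w.sum()

    @classmethod
    def from_run_config(cls, cfg) -> "GAConfig":
        return cls(population=cfg.ga_population, generations=cfg.ga_generations,
                   elite_fraction=cfg.elite_fraction, mutation_mean=cfg.mutation_mean,
                   mutation_sd=cfg.mutation_sd, horizon=cfg.horizon,
                   n_actions=cfg.n_actions, delta=cfg.delta)


def init_population(cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """(τ, η) array of uniformly random action indices."""
    return rng.integers(0, cfg.n_actions, size=(cfg.population, cfg.horizon))


def exhaustive_population(n_actions: int, horizon: int) -> np.ndarray:
    """All n^η action sequences (for brute-force cross-checks on tiny
    instances)."""
    grids = np.meshgrid(*([np.arange(n_actions)] * horizon), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def crossover(g1: np.ndarray, g2: np.ndarray, w: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover: cut index i ∈ [2, η] sampled from w; child 1 is
    g1[1..i−1] + g2[i..η] (1-indexed), and symmetrically for child 2."""
    eta = len(g1)
    i = 2 + int(rng.choice(eta - 1, p=w))  # i in [2, eta]
    c1 = np.concatenate([g1[: i - 1], g2[i - 1:]])
    c2 = np.concatenate([g2[: i - 1], g1[i - 1:]])
    return c1, c2


def mutate(gene: np.ndarray, cfg: GAConfig, rng: np.random.Generator,
           force: bool = False) -> np.ndarray:
    """With probability ~ clip(Normal(μ, φ), 0, 1), replace one uniformly
    chosen position with a *different* uniformly chosen action."""
    p = 1.0 if force else float(np.clip(rng.normal(cfg.mutation_mean, cfg.mutation_sd), 0.0, 1.0))
    out = gene.copy()
    if rng.random() < p:
        pos = int(rng.integers(len(gene)))
        new = int(rng.integers(cfg.n_actions - 1))
        if new >= out[pos]:
            new += 1
        out[pos] = new
    return out


def _selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    score = np.clip(1.0 - fitness, 0.0, None)
    s = score.sum()
    if s <= 0:
        return np.full(len(fitness), 1.0 / len(fitness))
    return score / s


def _crossover_batch(parents: np.ndarray, w: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Pairwise single-point crossover of consecutive parent pairs (batched
    equivalent of :func:`crossover`); an odd trailing parent passes through."""
    n, eta = parents.shape
    children = parents.copy()
    n_pairs = n // 2
    if n_pairs:
        cuts = 2 + rng.choice(eta - 1, size=n_pairs, p=w)      # i in [2, eta]
        cols = np.arange(eta)[None, :]
        tail = cols >= (cuts[:, None] - 1)                     # positions i..eta
        g1 = parents[0:2 * n_pairs:2]
        g2 = parents[1:2 * n_pairs:2]
        children[0:2 * n_pairs:2] = np.where(tail, g2, g1)
        children[1:2 * n_pairs:2] = np.where(tail, g1, g2)
    return children


def _mutate_batch(genes: np.ndarray, cfg: GAConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Batched equivalent of :func:`mutate`."""
    n, eta = genes.shape
    p = np.clip(rng.normal(cfg.mutation_mean, cfg.mutation_sd, size=n), 0.0, 1.0)
    hit = rng.random(n) < p
    out = genes.copy()
    idx = np.nonzero(hit)[0]
    if idx.size:
        pos = rng.integers(eta, size=idx.size)
        new = rng.integers(cfg.n_actions - 1, size=idx.size)
        new = new + (new >= out[idx, pos])     # skip the current action
        out[idx, pos] = new
    return out


def next_generation(genes: np.ndarray, fitness: np.ndarray, cfg: GAConfig,
                    rng: np.random.Generator,
                    evaluator: Callable[[np.ndarray], np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Elites (lowest objective) survive unchanged; the remaining slots are
    filled by fitness-proportionate parents recombined and mutated, then
    re-scored."""
    order = np.argsort(fitness, kind="stable")
    n_elite = min(cfg.n_elite, cfg.population)
    elite_g, elite_f = genes[order[:n_elite]], fitness[order[:n_elite]]
    n_rest = cfg.population - n_elite
    if n_rest == 0:
        return elite_g, elite_f
    p = _selection_probabilities(fitness)
    parents = genes[rng.choice(len(genes), size=n_rest, p=p)]
    children = _mutate_batch(_crossover_batch(parents, cfg.cut_weights(), rng),
                             cfg, rng)
    child_f = evaluator(children)
    return (np.concatenate([elite_g, children]),
            np.concatenate([elite_f, child_f]))


def _heading_angle(agent) -> float:
    u = agent.heading
    return math.atan2(u[1], u[0])


_DIR_CACHE: dict[int, np.ndarray] = {}
_TRIU_CACHE: dict[int, tuple] = {}


def _dirs(n_actions: int) -> np.ndarray:
    d = _DIR_CACHE.get(n_actions)
    if d is None:
        d = _DIR_CACHE[n_actions] = action_directions(n_actions)
    return d


def _triu(m: int) -> tuple:
    t = _TRIU_CACHE.get(m)
    if t is None:
        t = _TRIU_CACHE[m] = np.triu_indices(m, k=1)
    return t


try:  # compiled rollout kernel; the numpy path below is the reference
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _objective_kernel(genes, fl, fv, speed0, fallback, npos, nvel, nang,
                      ncos, nsin, thr_fn, nn_counts, norm_pairs,
                      delta, zeta, eta, dirs):  # pragma: no cover - jitted
    B = genes.shape[0]
    m = npos.shape[0]
    n_patch = m + 1
    two_pi = 2.0 * np.pi
    obj = np.zeros(B)
    for b in range(B):
        px, py = fl[0], fl[1]
        vx, vy = fv[0], fv[1]
        speed = speed0
        acc = 0.0
        for t in range(eta + 1):
            if t > 0:
                a = genes[b, t - 1]
                nx = vx + delta * dirs[a, 0]
                ny = vy + delta * dirs[a, 1]
                snew = (nx * nx + ny * ny) ** 0.5
                target = speed if speed > 0 else delta
                if snew > 0:
                    nx *= target / snew
                    ny *= target / snew
                else:
                    nx = 0.0
                    ny = 0.0
                vx, vy = nx, ny
                speed = (vx * vx + vy * vy) ** 0.5
                px += vx
                py += vy
            fang = np.arctan2(vy, vx) if speed > 0 else fallback
            mu = np.arctan2(nsin + np.sin(fang), ncos + np.cos(fang))
            d0 = fang - mu
            d0 = d0 - two_pi * np.floor((d0 + np.pi) / two_pi)
            sq = d0 * d0
            count = nn_counts[t]
            fcx = px + vx
            fcy = py + vy
            for j in range(m):
                dn = nang[j] - mu
                dn = dn - two_pi * np.floor((dn + np.pi) / two_pi)
                sq += dn * dn
                ncx = npos[j, 0] + (t + 1) * nvel[j, 0]
                ncy = npos[j, 1] + (t + 1) * nvel[j, 1]
                dd = ((fcx - ncx) ** 2 + (fcy - ncy) ** 2) ** 0.5
                if dd <= thr_fn[j]:
                    count += 1.0
            F = sq / (n_patch * two_pi)
            C = count / norm_pairs if norm_pairs > 0 else 0.0
            if C > 1.0:
                C = 1.0
            acc += zeta * F + (1.0 - zeta) * C
        obj[b] = acc / (eta + 1)
    return obj


class _ScenarioData:
    """Per-scenario constants of the rollout objective, computed once and
    reused across GA generations."""

    __slots__ = ("fl", "fv", "speed0", "fallback", "npos", "nvel", "nang",
                 "ncos", "nsin", "thr_fn", "nn_counts", "norm_pairs", "m")

    def __init__(self, scenario, cfg: GAConfig):
        focal = scenario.focal
        nbrs = list(scenario.neighbors)
        eta = cfg.horizon
        self.m = m = len(nbrs)
        self.norm_pairs = (m + 1) // 2
        self.fl = focal.l.astype(np.float64)
        self.fv = focal.v.astype(np.float64)
        self.speed0 = float(focal.speed)
        self.fallback = _heading_angle(focal)
        if m == 0:
            return
        self.npos = np.array([p.l for p in nbrs], dtype=np.float64)
        self.nvel = np.array([p.v for p in nbrs], dtype=np.float64)
        self.nang = np.array([_heading_angle(p) for p in nbrs])
        self.ncos = float(np.cos(self.nang).sum())
        self.nsin = float(np.sin(self.nang).sum())
        nh = np.array([p.h for p in nbrs])
        nw = np.array([p.w for p in nbrs])
        self.thr_fn = np.maximum(focal.h + nh, focal.w + nw) / 2.0
        iu, ju = _triu(m)
        thr_nn = np.maximum(nh[iu] + nh[ju], nw[iu] + nw[ju]) / 2.0
        # predictive neighbor-neighbor collision counts for each step
        self.nn_counts = np.empty(eta + 1)
        for t in range(eta + 1):
            c = self.npos + (t + 1) * self.nvel
            dd = np.hypot(*(c[iu] - c[ju]).T) if m > 1 else np.empty(0)
            self.nn_counts[t] = np.count_nonzero(dd <= thr_nn)


def _evaluate_pre(genes: np.ndarray, pre: _ScenarioData, zeta: float,
                  cfg: GAConfig, force_numpy: bool = False) -> np.ndarray:
    B = len(genes)
    eta = cfg.horizon
    m = pre.m
    n_patch = m + 1
    norm_pairs = pre.norm_pairs

    if m == 0:
        # a lone focal agent: F over one agent is 0 and no pair can collide
        return np.zeros(B)

    npos, nvel, nang = pre.npos, pre.nvel, pre.nang
    ncos, nsin = pre.ncos, pre.nsin
    thr_fn, nn_counts = pre.thr_fn, pre.nn_counts
    fallback = pre.fallback
    if _HAVE_NUMBA and not force_numpy:
        return _objective_kernel(
            np.ascontiguousarray(genes, dtype=np.int64),
            pre.fl, pre.fv, pre.speed0, float(fallback),
            npos, nvel, nang, ncos, nsin,
            thr_fn, nn_counts, int(norm_pairs),
            float(cfg.delta), float(zeta), int(eta),
            _dirs(cfg.n_actions).astype(np.float64))

    dirs = _dirs(cfg.n_actions)
    pos = np.tile(pre.fl, (B, 1))
    vel = np.tile(pre.fv, (B, 1))
    speed = np.full(B, pre.speed0)

    obj = np.zeros(B)
    for t in range(eta + 1):
        if t > 0:
            d = dirs[genes[:, t - 1]]
            vnew = vel + cfg.delta * d
            snew = np.hypot(vnew[:, 0], vnew[:, 1])
            target = np.where(speed > 0, speed, cfg.delta)
            scale = np.divide(target, snew, out=np.zeros_like(snew),
                              where=snew > 0)
            vel = vnew * scale[:, None]
            speed = np.hypot(vel[:, 0], vel[:, 1])
            pos = pos + vel
        # collective-motion term
        fang = np.where(speed > 0, np.arctan2(vel[:, 1], vel[:, 0]), fallback)
        mu = np.arctan2(nsin + np.sin(fang), ncos + np.cos(fang))
        dev_f = np.pi - np.mod(np.pi - (fang - mu), TWO_PI)
        dev_n = np.pi - np.mod(np.pi - (nang[None, :] - mu[:, None]), TWO_PI)
        sq = dev_f ** 2 + (dev_n ** 2).sum(axis=1)
        F = sq / (n_patch * TWO_PI)
        # collision-avoidance term (predictive centers)
        fc = pos + vel
        nc = npos + (t + 1) * nvel
        dd = np.hypot(fc[:, None, 0] - nc[None, :, 0],
                      fc[:, None, 1] - nc[None, :, 1])
        counts = (dd <= thr_fn[None, :]).sum(axis=1) + nn_counts[t]
        C = np.minimum(1.0, counts / norm_pairs)
        obj += zeta * F + (1.0 - zeta) * C
    return obj / (eta + 1)


def evaluate_genes(genes: np.ndarray, scenario, zeta: float,
                   cfg: GAConfig, force_numpy: bool = False) -> np.ndarray:
    """Local CMCA objective of each gene's rollout (vectorized over genes).

    The focal agent executes the gene's actions with the steering update
    (velocity renormalized to its running speed); neighbors are ballistic.
    Per step, F is the circular heading variance of the patch scaled by 1/2π
    and C the predictive colliding-pair count over ⌊(m+1)/2⌋; the objective
    is the mean of ζF + (1−ζ)C over steps 0..η.
    """
    return _evaluate_pre(genes, _ScenarioData(scenario, cfg), zeta, cfg,
                         force_numpy=force_numpy)


def plan(scenario, cfg: GAConfig, zeta: float, rng: np.random.Generator,
         initial_population: Optional[np.ndarray] = None,
         trace: Optional[list] = None) -> tuple[Action, float]:
    """Run the GA and return (first action of the best gene, its score).

    The returned score is 1 − best objective, clipped to [0, 1]; elitism
    makes the best objective non-increasing across generations.
    """
    if not scenario.neighbors and initial_population is None and trace is None:
        # every gene has objective 0 for a lone focal agent; skip the search
        return make_action(int(rng.integers(cfg.n_actions)), cfg.n_actions), 1.0
    genes = init_population(cfg, rng) if initial_population is None \
        else np.asarray(initial_population)
    pre = _ScenarioData(scenario, cfg)
    fitness = _evaluate_pre(genes, pre, zeta, cfg)

    def evaluator(g):
        return _evaluate_pre(g, pre, zeta, cfg)

    for gen in range(cfg.generations):
        if trace is not None:
            trace.append((gen, float(fitness.min()), float(fitness.mean())))
        genes, fitness = next_generation(genes, fitness, cfg, rng, evaluator)
    if trace is not None:
        trace.append((cfg.generations, float(fitness.min()), float(fitness.mean())))
    best = int(np.argmin(fitness))
    score = float(np.clip(1.0 - fitness[best], 0.0, 1.0))
    return make_action(int(genes[best, 0]), cfg.n_actions), score
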