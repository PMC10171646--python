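"""Swarm-level order and collision metrics and the combined objective.

The collective-motion (CM) metric F is the circular variance of the agents'
movement headings scaled by 1/2π: deviations of each heading from the
population's circular-mean heading are wrapped to (−π, π], squared, and
averaged.  Perfect alignment gives F = 0; isotropic headings give
F → (1/2π)(π²/3) ≈ 0.524.

The collision-avoidance (CA) metric C is the number of colliding pairs in a
step divided by the largest possible number of simultaneous collisions,
⌊|P|/2⌋ disjoint pairs, so C ∈ [0, 1].

The combined objective is the time-mean of ζF_t + (1−ζ)C_t over a window;
"scores" are complements (1 − value) clipped to [0, 1], so 1 means a
perfectly aligned, collision-free swarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoreSeries", "cm_metric", "ca_metric", "cmca_objective",
           "local_objective", "cm_from_headings", "collision_pair_count"]

TWO_PI = 2.0 * np.pi


def _wrap_pi(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (−π, π]."""
    return np.pi - np.mod(np.pi - x, TWO_PI)


def cm_from_headings(angles: np.ndarray) -> float:
    """F from an array of heading angles [rad]."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("CM metric undefined for an empty population")
    mean = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    dev = _wrap_pi(angles - mean)
    return float(np.mean(dev ** 2) / TWO_PI)


def cm_metric(agents: Sequence) -> float:
    """CM order metric F over a population of agents (uses each agent's
    heading; stopped agents contribute their last heading)."""
    if len(agents) == 0:
        raise ValueError("CM metric undefined for an empty population")
    heads = np.array([a.heading for a in agents])
    return cm_from_headings(np.arctan2(heads[:, 1], heads[:, 0]))


def collision_pair_count(agents: Sequence, env=None) -> int:
    """Number of colliding pairs under the predictive collision condition
    (post-move centers closer than max(h1+h2, w1+w2)/2)."""
    from .dynamics import detect_collisions  # local import to avoid a cycle
    return len(detect_collisions(list(agents), env))


def ca_metric(agents: Sequence, env=None) -> float:
    """Normalized collision rate C = colliding pairs / ⌊|P|/2⌋ ∈ [0, 1]."""
    n = len(agents)
    if n < 2:
        return 0.0
    return min(1.0, collision_pair_count(agents, env) / (n // 2))


def ca_from_pair_count(n_pairs: int, n_agents: int) -> float:
    if n_agents < 2:
        return 0.0
    return min(1.0, n_pairs / (n_agents // 2))


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


@dataclass
class ScoreSeries:
    """Per-tick F_t and C_t for a run, with derived complement scores."""
    zeta: float = 0.5
    F: list = field(default_factory=list)
    C: list = field(default_factory=list)

    def record(self, f_t: float, c_t: float) -> None:
        self.F.append(float(f_t))
        self.C.append(float(c_t))

    @property
    def cm_score(self) -> np.ndarray:
        return np.clip(1.0 - np.asarray(self.F), 0.0, 1.0)

    @property
    def ca_score(self) -> np.ndarray:
        return np.clip(1.0 - np.asarray(self.C), 0.0, 1.0)

    @property
    def cmca_score(self) -> np.ndarray:
        f, c = np.asarray(self.F), np.asarray(self.C)
        return np.clip(1.0 - (self.zeta * f + (1.0 - self.zeta) * c), 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": np.arange(len(self.F)),
            "F": self.F, "C": self.C,
            "cm_score": self.cm_score,
            "ca_score": self.ca_score,
            "cmca_score": self.cmca_score,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cmca_objective(series: ScoreSeries, t0: int = 0, tf: int | None = None) -> float:
    """Time-mean of ζF_t + (1−ζ)C_t over ticks [t0, tf] (inclusive).

    Averaging (rather than summing) keeps the complement score in [0, 1]
    independent of run length.
    """
    f = np.asarray(series.F, dtype=float)
    c = np.asarray(series.C, dtype=float)
    if tf is None:
        tf = len(f) - 1
    if not t0 < tf:
        raise ValueError("need t0 < tf")
    f, c = f[t0:tf + 1], c[t0:tf + 1]
    return float(np.mean(series.zeta * f + (1.0 - series.zeta) * c))


def cmca_score(series: ScoreSeries, t0: int = 0, tf: int | None = None) -> float:
    return _clip01(1.0 - cmca_objective(series, t0, tf))


def local_objective(rollout: Sequence[Sequence], zeta: float, env=None) -> float:
    """Planner fitness: the CMCA objective restricted to a focal agent and its
    local environment over a short rollout (lower is better).

    ``rollout`` is a sequence of per-step agent snapshots (lists of agents,
    focal included).  A single-agent patch has F = 0 by definition and the
    objective reduces to the collision term.
    """
    terms = []
    for agents in rollout:
        f = 0.0 if len(agents) < 2 else cm_metric(agents)
        c = ca_metric(agents, env)
        terms.append(zeta * f + (1.0 - zeta) * c)
    return float(np.mean(terms))
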