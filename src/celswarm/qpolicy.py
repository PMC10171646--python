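"""Tabular stochastic policy over the discretized vision state space.

The table is sparse: states never visited behave as a uniform row (each of
the n actions weighted 1/n), which is observationally identical to a table
initialized with every possible state but feasible in memory.  Updates are
additive-positive — the planner's score (1 − local objective, so larger is
better) times the learning rate λ is added to the chosen action's weight;
there is no temporal-difference bootstrap term.  Action selection samples
proportionally to the row (stochastic mode) or takes the argmax (greedy).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Policy

logger = logging.getLogger(__name__)

__all__ = ["QTable", "QTablePolicy", "RandomWalkPolicy", "save", "load"]

_FORMAT_VERSION = 1


@dataclass
class QTable:
    """Sparse state → action-weight table with a uniform default row."""
    n_actions: int = 24
    learning_rate: float = 0.1       # λ
    bin_width: float = 0.01
    max_neighbors: int = 8           # k
    table: dict = field(default_factory=dict)
    visit_counts: dict = field(default_factory=dict)

    def row(self, state) -> np.ndarray:
        """Current weights for a state (uniform if unvisited); a copy."""
        r = self.table.get(state)
        if r is None:
            return np.full(self.n_actions, 1.0 / self.n_actions)
        return r.copy()

    def probabilities(self, state) -> np.ndarray:
        r = self.table.get(state)
        if r is None:
            return np.full(self.n_actions, 1.0 / self.n_actions)
        s = r.sum()
        if s <= 0 or not np.isfinite(s):
            logger.warning("Q row for %s sums to %s; falling back to uniform", state, s)
            return np.full(self.n_actions, 1.0 / self.n_actions)
        return r / s

    def select_action(self, state, rng: np.random.Generator,
                      mode: str = "stochastic") -> int:
        p = self.probabilities(state)
        if mode == "greedy":
            return int(np.argmax(p))   # argmax takes the lowest index on ties
        if mode != "stochastic":
            raise ValueError(f"unknown selection mode {mode!r}")
        return int(rng.choice(self.n_actions, p=p))

    def update(self, state, action: int, score: float) -> "QTable":
        """q[state][action] += λ·score; score is the planner's complement
        objective in [0, 1]."""
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {score}")
        r = self.table.get(state)
        if r is None:
            r = np.full(self.n_actions, 1.0 / self.n_actions)
            self.table[state] = r
        r[int(action)] += self.learning_rate * score
        self.visit_counts[state] = self.visit_counts.get(state, 0) + 1
        return self

    def config_header(self) -> dict:
        return {"version": _FORMAT_VERSION, "n_actions": self.n_actions,
                "learning_rate": self.learning_rate,
                "bin_width": self.bin_width, "max_neighbors": self.max_neighbors}


def save(q: QTable, path) -> None:
    """Serialize to a gzip-compressed JSON archive with a config header."""
    payload = {
        "config": q.config_header(),
        "states": [list(s) for s in q.table],
        "rows": [q.table[s].tolist() for s in q.table],
        "visits": [q.visit_counts.get(s, 0) for s in q.table],
    }
    with gzip.open(path, "wt") as fh:
        json.dump(payload, fh)


def load(path, expect: QTable | None = None) -> QTable:
    """Load a policy archive; refuses a file whose configuration (bin width,
    action count, neighbor slots) does not match ``expect``."""
    with gzip.open(path, "rt") as fh:
        payload = json.load(fh)
    hdr = payload["config"]
    if hdr.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported policy file version {hdr.get('version')}")
    q = QTable(n_actions=hdr["n_actions"], learning_rate=hdr["learning_rate"],
               bin_width=hdr["bin_width"], max_neighbors=hdr["max_neighbors"])
    if expect is not None:
        for key in ("n_actions", "bin_width", "max_neighbors"):
            if getattr(expect, key) != getattr(q, key):
                raise ValueError(
                    f"policy file {key}={getattr(q, key)} does not match the "
                    f"current configuration {key}={getattr(expect, key)}")
    for s, r, v in zip(payload["states"], payload["rows"], payload["visits"]):
        state = tuple(s)
        q.table[state] = np.asarray(r, dtype=float)
        q.visit_counts[state] = int(v)
    return q


class QTablePolicy(Policy):
    """Policy view of a QTable for the simulator (stochastic or greedy)."""

    state_independent = False

    def __init__(self, q: QTable, mode: str = "stochastic"):
        self.q = q
        self.mode = mode
        self.n_actions = q.n_actions

    def select(self, state, rng: np.random.Generator) -> int:
        return self.q.select_action(state, rng, mode=self.mode)


class RandomWalkPolicy(Policy):
    """Uniform action choice, independent of the state — identical in law to
    an untrained QTable's stochastic policy."""

    state_independent = True

    def __init__(self, n_actions: int = 24):
        self.n_actions = n_actions

    def select(self, state, rng: np.random.Generator) -> int:
        return int(rng.integers(self.n_actions))
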