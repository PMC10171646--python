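"""Experiment suite: baselines, parameter sweeps, and policy explainability.

Baselines compare a trained policy (ζ = 0.5), an alignment-only policy
(ζ = 1, trained ignoring collisions) and the uniform random walk on the CM,
CA and combined CMCA scores over replicate full-population simulations.
Sensitivity sweeps re-evaluate a default-trained policy under different
population sizes, body aspect ratios and sensing radii (no retraining).
The explainability analysis fits a bagged ensemble of depth- or leaf-
constrained decision trees to (state, greedy action) pairs queried from the
policy and reports how well the ensemble reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .config import RunConfig, substream
from .dynamics import Policy, run_simulation
from .metrics import cmca_score
from .qpolicy import RandomWalkPolicy
from .training import generate_scenario
from .vision import sentinel_bin

__all__ = ["ExperimentGrid", "SurrogateDataset", "random_walk_policy",
           "run_replicates", "run_baseline_comparison", "run_sensitivity",
           "build_surrogate_dataset", "surrogate_accuracy_curve"]

SWEEPABLE = ("population_size", "aspect_ratio", "sensing_radius")


@dataclass
class ExperimentGrid:
    """One swept parameter and the values to evaluate it at."""
    parameter: str
    values: Sequence[float]
    reps: int = 30

    def __post_init__(self):
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}; "
                             f"expected one of {SWEEPABLE}")
        if len(self.values) == 0 or self.reps < 1:
            raise ValueError("need at least one grid value and one repetition")


@dataclass
class SurrogateDataset:
    """Rows of (expanded state features, greedy action label)."""
    X: np.ndarray
    y: np.ndarray


def random_walk_policy(n_actions: int = 24) -> RandomWalkPolicy:
    """Uniform-over-actions, state-independent baseline policy."""
    return RandomWalkPolicy(n_actions=n_actions)


def run_replicates(cfg: RunConfig, policy: Policy, reps: int,
                   seed_label: str = "sim") -> list:
    """Replicate full simulations with per-replicate seed substreams;
    returns the list of per-run score series."""
    out = []
    for rep in range(reps):
        rng = substream(cfg.seed, f"{seed_label}-{rep}")
        out.append(run_simulation(cfg, policy, rng).series)
    return out


def _summarize(series_list: list, zeta: float) -> dict:
    cm = np.array([s.cm_score for s in series_list])      # (reps, T+1)
    ca = np.array([s.ca_score for s in series_list])
    cmca = np.array([s.cmca_score for s in series_list])
    return {
        "cm_mean": float(cm.mean()), "cm_sd": float(cm.mean(axis=1).std(ddof=1)),
        "ca_mean": float(ca.mean()), "ca_sd": float(ca.mean(axis=1).std(ddof=1)),
        "cmca_mean": float(cmca.mean()), "cmca_sd": float(cmca.mean(axis=1).std(ddof=1)),
        "cm_final": float(cm[:, -1].mean()),
        "ca_final": float(ca[:, -1].mean()),
        "cmca_final": float(cmca[:, -1].mean()),
    }


def run_baseline_comparison(policies: dict, cfg: RunConfig, reps: int = 30
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score tables and per-step curves for a set of named policies.

    Returns (summary, curves): the summary holds over-time and final-step
    mean ± sd of each score per policy; the curves hold per-step means and
    standard deviations over replicates.
    """
    rows, curve_rows = [], []
    for name, policy in policies.items():
        series = run_replicates(cfg, policy, reps, seed_label=f"baseline-{name}")
        s = _summarize(series, cfg.zeta)
        rows.append({"policy": name, **s})
        cm = np.array([x.cm_score for x in series])
        ca = np.array([x.ca_score for x in series])
        cmca = np.array([x.cmca_score for x in series])
        for t in range(cm.shape[1]):
            curve_rows.append({
                "policy": name, "t": t,
                "cm_mean": cm[:, t].mean(), "cm_sd": cm[:, t].std(ddof=1),
                "ca_mean": ca[:, t].mean(), "ca_sd": ca[:, t].std(ddof=1),
                "cmca_mean": cmca[:, t].mean(), "cmca_sd": cmca[:, t].std(ddof=1)})
    return pd.DataFrame(rows), pd.DataFrame(curve_rows)


def _apply_grid_value(cfg: RunConfig, parameter: str, value: float) -> RunConfig:
    if parameter == "population_size":
        return replace(cfg, population_size=int(value))
    if parameter == "sensing_radius":
        return replace(cfg, sensing_radius=float(value))
    # aspect ratio h/w: body height is held fixed so the sensing radius in
    # body lengths does not change; width varies
    return replace(cfg, body_width=cfg.body_height / float(value))


def run_sensitivity(grid: ExperimentGrid, policy: Policy, cfg: RunConfig
                    ) -> pd.DataFrame:
    """Mean ± sd CMCA score per grid value for a policy trained at the
    default configuration (evaluation only, no retraining)."""
    rows = []
    for value in grid.values:
        sub = _apply_grid_value(cfg, grid.parameter, value)
        series = run_replicates(sub, policy, grid.reps,
                                seed_label=f"sweep-{grid.parameter}-{value}")
        scores = [cmca_score(s) for s in series]
        rows.append({
            grid.parameter: value,
            "density": sub.population_size / (sub.width * sub.height),
            "cmca_mean": float(np.mean(scores)),
            "cmca_sd": float(np.std(scores, ddof=1)) if grid.reps > 1 else 0.0,
            "reps": grid.reps})
    return pd.DataFrame(rows)


def build_surrogate_dataset(policy, cfg: RunConfig, n_cases: int,
                            rng: np.random.Generator) -> SurrogateDataset:
    """Random scenarios encoded to state features with the policy's greedy
    action as the label.  Sentinel (absent-slot) bins are mapped to −1 so the
    features stay small and finite."""
    sent = sentinel_bin(cfg.state_bin)
    X = np.empty((n_cases, 4 * cfg.max_neighbors), dtype=np.int32)
    y = np.empty(n_cases, dtype=np.int32)
    for i in range(n_cases):
        sc = generate_scenario(cfg, rng)
        state = sc.encoded_state(cfg)
        feat = np.asarray(state, dtype=np.int32)
        feat[feat == sent] = -1
        X[i] = feat
        if hasattr(policy, "q"):
            y[i] = policy.q.select_action(state, rng, mode="greedy")
        else:
            y[i] = policy.select(state, rng)
    return SurrogateDataset(X=X, y=y)


def surrogate_accuracy_curve(dataset: SurrogateDataset,
                             constraint: dict, trees: int = 1000,
                             holdout: float = 0.2,
                             seed: int = 0) -> pd.DataFrame:
    """Accuracy of a bagged tree ensemble at reproducing the policy's action,
    as a function of a complexity constraint.

    ``constraint`` is {"max_depth": [...]} or {"max_leaves": [...]}; for each
    value an ensemble of that complexity is fit on a training split and
    scored on the holdout.
    """
    (key, values), = constraint.items()
    if key not in ("max_depth", "max_leaves"):
        raise ValueError("constraint must be 'max_depth' or 'max_leaves'")
    stratify = dataset.y if np.unique(dataset.y).size > 1 else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        dataset.X, dataset.y, test_size=holdout, random_state=seed,
        stratify=stratify)
    rows = []
    for v in values:
        kwargs = {"max_depth": int(v)} if key == "max_depth" \
            else {"max_leaf_nodes": int(v)}
        rf = RandomForestClassifier(n_estimators=trees, random_state=seed,
                                    n_jobs=1, **kwargs)
        rf.fit(X_tr, y_tr)
        rows.append({key: int(v), "accuracy": float(rf.score(X_te, y_te))})
    return pd.DataFrame(rows)
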