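"""Run configuration and reproducible random-number substreams.

All model parameters live in a single :class:`RunConfig` whose defaults are
the locust-swarm reference configuration: a 5 m x 5 m toroidal arena, 30
rectangular agents of body 0.07 m x 0.01 m, sensing radius 0.21 m, 15-degree
action discretization, and the learning hyper-parameters of the collective
evolution learning (CEL) loop.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "save_config", "substream"]


@dataclass
class RunConfig:
    # environment
    width: float = 5.0            # W, arena width [m]
    height: float = 5.0           # H, arena height [m]
    population_size: int = 30     # |P|
    v_init_max: float = 0.15      # initial velocity ~ (U[0, v_init_max], U[0, v_init_max]) [m/s]
    body_height: float = 0.07     # h, body extent along heading [m]
    body_width: float = 0.01      # w, body extent across heading [m]
    delta: float = 0.05           # δ, action influence weight
    sensing_radius: float = 0.21  # r [m]
    zeta: float = 0.5             # ζ, CM weight vs CA weight
    n_steps: int = 500            # T, ticks per simulation
    # state/action discretization
    max_neighbors: int = 8        # k, neighbor slots in the encoded state
    state_bin: float = 0.01       # state-space discretization [rad or rad/step]
    action_step_deg: float = 15.0  # action-space discretization [degrees]
    # CEL loop
    z_train: int = 10_000_000     # total training scenarios
    z_validate: int = 100_000     # validation scenarios per round
    z_test: int = 450_000         # testing budget (reporting uses `reps` full runs)
    kappa: float = 0.05           # κ, TVD stop threshold
    knn_neighbors: int = 3        # y, KNN neighbors for performance estimation
    max_rounds: int = 10          # cap on train/validate rounds
    n_probes: int = 10_000        # uniform probes of the state-descriptor space
    learning_rate: float = 0.1    # λ (not fixed by the reference configuration)
    # GA planner
    mutation_mean: float = 0.1    # μ
    mutation_sd: float = 0.05     # φ
    ga_generations: int = 10      # g
    ga_population: int = 20       # τ
    horizon: int = 5              # η, planning steps
    elite_fraction: float = 0.05  # ι, royalty rate
    # plumbing
    seed: int = 0
    signed_theta: bool = False    # deviation flag: signed angular position
    raw_velocity_update: bool = False  # raw Eq-4 mode (no speed renormalization)

    @property
    def n_actions(self) -> int:
        n = 360.0 / self.action_step_deg
        return int(round(n))

    def validate(self) -> "RunConfig":
        def _pos(name):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive, got {getattr(self, name)}")
        for name in ("width", "height", "population_size", "v_init_max", "body_height",
                     "body_width", "sensing_radius", "n_steps", "max_neighbors",
                     "state_bin", "action_step_deg", "z_train", "z_validate", "z_test",
                     "knn_neighbors", "max_rounds", "n_probes", "ga_generations",
                     "ga_population", "horizon", "mutation_mean"):
            _pos(name)
        if not 0 < self.delta <= 1:
            raise ValueError(f"config field 'delta' must be in (0, 1], got {self.delta}")
        if not 0 <= self.zeta <= 1:
            raise ValueError(f"config field 'zeta' must be in [0, 1], got {self.zeta}")
        if not 0 <= self.kappa <= 1:
            raise ValueError(f"config field 'kappa' must be in [0, 1], got {self.kappa}")
        if not 0 <= self.learning_rate <= 1:
            raise ValueError(f"config field 'learning_rate' must be in [0, 1], got {self.learning_rate}")
        if not 0 <= self.elite_fraction <= 1:
            raise ValueError(f"config field 'elite_fraction' must be in [0, 1], got {self.elite_fraction}")
        if self.mutation_sd < 0:
            raise ValueError(f"config field 'mutation_sd' must be >= 0, got {self.mutation_sd}")
        if abs(360.0 / self.action_step_deg - self.n_actions) > 1e-9:
            raise ValueError("action_step_deg must divide 360")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()


def load_config(path) -> RunConfig:
    """Load a YAML config; an empty file yields the full default configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from a master seed.

    Changing how many draws one consumer makes never perturbs another
    consumer's stream, and adding replicates does not shift earlier ones.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
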