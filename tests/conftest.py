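import numpy as np
import pytest

from celswarm import AgentState, EnvironmentConfig, RunConfig


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def small_cfg():
    """Reduced world for fast dynamics tests."""
    return RunConfig(population_size=10, n_steps=50, seed=11)


@pytest.fixture
def env():
    return EnvironmentConfig(width=5.0, height=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_agent(id=0, l=(0.0, 0.0), v=(0.1, 0.0), h=0.07, w=0.01, r=0.21):
    return AgentState(id=id, l=np.array(l, dtype=float),
                      v=np.array(v, dtype=float), h=h, w=w, r=r)


@pytest.fixture
def agent_factory():
    return make_agent


def boundary_span_oracle(focal, neighbor, n_points=10_000):
    """ψ oracle: densely sample the neighbor rectangle's boundary and return
    the maximum pairwise angular span of the sampled directions."""
    head = neighbor.heading
    perp = np.array([-head[1], head[0]])
    t = np.linspace(0.0, 1.0, n_points // 4)
    h2, w2 = neighbor.h / 2, neighbor.w / 2
    edges = []
    for a, b in [((-h2, -w2), (-h2, w2)), ((-h2, w2), (h2, w2)),
                 ((h2, w2), (h2, -w2)), ((h2, -w2), (-h2, -w2))]:
        pa = a[0] * head + a[1] * perp
        pb = b[0] * head + b[1] * perp
        edges.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
    pts = neighbor.l[None, :] + np.concatenate(edges)
    rel = pts - focal.l[None, :]
    bearings = np.sort(np.arctan2(rel[:, 1], rel[:, 0]))
    # the occupied arc is the circle minus the largest empty gap
    gaps = np.diff(bearings)
    wrap_gap = bearings[0] + 2 * np.pi - bearings[-1]
    return float(2 * np.pi - max(gaps.max(), wrap_gap))
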