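"""Vision-based perception of rectangular agents in a toroidal arena.

Each agent is a rectangle of body height ``h`` (along its heading) and width
``w`` (across it).  A focal agent perceives each neighbor within its metric
sensing radius through a four-tuple γ = (ψ, ψ̇, θ, θ̇):

* ψ — the angle subtended by the neighbor's body on the focal "retina",
  computed as the maximum angle between any two corner direction vectors;
* θ — the unsigned angular position of the neighbor's center relative to the
  focal heading (arccos of the normalized dot product, so θ ∈ [0, π] and the
  agent cannot tell left from right);
* ψ̇, θ̇ — one-step backward finite differences of the above.

Neighbors whose angular extent is fully hidden behind strictly nearer
neighbors are dropped ("fully latent"); partial occlusion is ignored.
All relative positions use the minimal-image convention on the torus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentConfig", "AgentState", "VisionTuple", "CornerSet",
    "corner_positions", "subtended_angle", "angular_position",
    "local_environment", "occlusion_filter", "observe", "encode_state",
    "sentinel_bin", "minimal_image",
]


@dataclass
class EnvironmentConfig:
    """Toroidal arena of width W and height H (periodic in both axes)."""
    width: float = 5.0
    height: float = 5.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("environment dimensions must be positive")


@dataclass
class AgentState:
    """One agent: center position l, velocity v, acceleration a, body h x w,
    sensing radius r.  ``last_heading`` retains the most recent nonzero
    heading so that a stopped agent keeps a defined orientation."""
    id: int
    l: np.ndarray
    v: np.ndarray
    a: np.ndarray = field(default_factory=lambda: np.zeros(2))
    h: float = 0.07
    w: float = 0.01
    r: float = 0.21
    last_heading: Optional[np.ndarray] = None

    def __post_init__(self):
        self.l = np.asarray(self.l, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.last_heading is None:
            s = float(np.hypot(*self.v))
            if s > 0:
                self.last_heading = self.v / s

    @property
    def speed(self) -> float:
        return float(np.hypot(*self.v))

    @property
    def heading(self) -> np.ndarray:
        """Unit heading: current velocity direction, else the last nonzero
        heading, else +x (flagged)."""
        s = self.speed
        if s > 0:
            u = self.v / s
            self.last_heading = u
            return u
        if self.last_heading is not None:
            return self.last_heading
        logger.debug("agent %s has no heading history; defaulting to +x", self.id)
        return np.array([1.0, 0.0])


@dataclass(frozen=True)
class VisionTuple:
    """Per-neighbor visual observation γ = (ψ, ψ̇, θ, θ̇).

    ``distance`` (center-to-center, minimal image) is carried along for the
    canonical slot ordering and occlusion bookkeeping; it is not part of the
    encoded state.
    """
    psi: float
    psi_dot: float
    theta: float
    theta_dot: float
    neighbor_id: int
    distance: float = math.nan


@dataclass
class CornerSet:
    """Lab-frame corners ρ_1..ρ_4 of a neighbor and, when a focal agent is
    given, the focal-frame vectors χ_i = ρ_i − l_o (minimal image)."""
    rho: np.ndarray                      # (4, 2)
    chi: Optional[np.ndarray] = None     # (4, 2)


def minimal_image(disp: np.ndarray, env: Optional[EnvironmentConfig]) -> np.ndarray:
    """Wrap displacement components into [−W/2, W/2) x [−H/2, H/2)."""
    if env is None:
        return np.asarray(disp, dtype=float)
    disp = np.array(disp, dtype=float)
    disp[..., 0] -= env.width * np.round(disp[..., 0] / env.width)
    disp[..., 1] -= env.height * np.round(disp[..., 1] / env.height)
    return disp


def _corner_offsets(head: np.ndarray, h: float, w: float) -> np.ndarray:
    """Offsets of the four corners from the body center, (4, 2)."""
    perp = np.array([-head[1], head[0]])
    signs_h = np.array([-1.0, 1.0, -1.0, 1.0])
    signs_w = np.array([1.0, 1.0, -1.0, -1.0])
    return signs_h[:, None] * (h / 2) * head + signs_w[:, None] * (w / 2) * perp


def corner_positions(neighbor: AgentState, focal: Optional[AgentState] = None,
                     env: Optional[EnvironmentConfig] = None) -> CornerSet:
    """Four lab-frame corners of the neighbor's h x w body rectangle, aligned
    with its heading; focal-frame vectors when ``focal`` is given."""
    offs = _corner_offsets(neighbor.heading, neighbor.h, neighbor.w)
    rho = neighbor.l[None, :] + offs
    chi = None
    if focal is not None:
        center = minimal_image(neighbor.l - focal.l, env)
        chi = center[None, :] + offs
    return CornerSet(rho=rho, chi=chi)


def _point_in_body(disp: np.ndarray, head: np.ndarray, h: float, w: float) -> bool:
    along = float(disp @ head)
    across = float(disp @ np.array([-head[1], head[0]]))
    return abs(along) <= h / 2 and abs(across) <= w / 2


_PAIR_I, _PAIR_J = np.triu_indices(4, k=1)


def subtended_angle(focal: AgentState, neighbor: AgentState,
                    env: Optional[EnvironmentConfig] = None) -> float:
    """Angle ψ subtended by the neighbor's body rectangle at the focal center:
    the maximum angle between any pair of corner vectors in the focal frame."""
    center = minimal_image(neighbor.l - focal.l, env)
    if not np.any(center):
        raise ValueError("focal and neighbor centers coincide; ψ undefined")
    if _point_in_body(center, neighbor.heading, neighbor.h, neighbor.w):
        logger.warning("focal center inside neighbor %s body; ψ = π", neighbor.id)
        return math.pi
    chi = center[None, :] + _corner_offsets(neighbor.heading, neighbor.h, neighbor.w)
    u = chi / np.linalg.norm(chi, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", u[_PAIR_I], u[_PAIR_J]), -1.0, 1.0)
    return float(np.max(np.arccos(cosang)))


def angular_position(focal: AgentState, neighbor: AgentState,
                     env: Optional[EnvironmentConfig] = None,
                     signed: bool = False) -> float:
    """Unsigned bearing θ ∈ [0, π] of the neighbor's center off the focal
    heading.  With ``signed=True`` (a deviation from the reference model) the
    sign of the cross product is kept and θ ∈ (−π, π]."""
    disp = minimal_image(neighbor.l - focal.l, env)
    d = float(np.hypot(*disp))
    if d == 0:
        raise ValueError("focal and neighbor centers coincide; θ undefined")
    head = focal.heading
    theta = math.acos(max(-1.0, min(1.0, float(head @ disp) / d)))
    if signed:
        cross = head[0] * disp[1] - head[1] * disp[0]
        if cross < 0:
            theta = -theta
    return theta


def local_environment(focal: AgentState, population: Sequence[AgentState],
                      env: EnvironmentConfig) -> list[AgentState]:
    """Neighbors with minimal-image distance strictly below the focal sensing
    radius (the metric neighborhood P*)."""
    out = []
    for p in population:
        if p.id == focal.id:
            continue
        disp = minimal_image(p.l - focal.l, env)
        if float(np.hypot(*disp)) < focal.r:
            out.append(p)
    return out


def _angular_interval(center_disp: np.ndarray, head: np.ndarray,
                      h: float, w: float) -> tuple[float, float]:
    """Arc [lo, hi] of bearings occupied by a body rectangle seen from the
    origin; full circle if the origin lies inside the body."""
    if _point_in_body(center_disp, head, h, w):
        return (-math.pi, math.pi)
    chi = center_disp[None, :] + _corner_offsets(head, h, w)
    bearings = np.arctan2(chi[:, 1], chi[:, 0])
    b0 = math.atan2(center_disp[1], center_disp[0])
    offs = (bearings - b0 + math.pi) % (2 * math.pi) - math.pi
    return (b0 + float(offs.min()), b0 + float(offs.max()))


def _arc_covered(lo: float, hi: float, arcs: list[tuple[float, float]],
                 tol: float = 1e-12) -> bool:
    """True iff [lo, hi] on the circle is covered by the union of arcs."""
    if not arcs:
        return False
    # unwrap every arc into copies overlapping the [lo, hi] window
    segs = []
    for a, b in arcs:
        if b - a >= 2 * math.pi - tol:
            return True
        for shift in (-2 * math.pi, 0.0, 2 * math.pi):
            aa, bb = a + shift, b + shift
            if bb >= lo - tol and aa <= hi + tol:
                segs.append((max(aa, lo), min(bb, hi)))
    if not segs:
        return False
    segs.sort()
    cursor = lo
    for a, b in segs:
        if a > cursor + tol:
            return False
        cursor = max(cursor, b)
        if cursor >= hi - tol:
            return True
    return cursor >= hi - tol


def occlusion_filter(focal: AgentState, neighbors: Sequence[AgentState],
                     env: Optional[EnvironmentConfig] = None) -> list[AgentState]:
    """Drop neighbors that are fully latent: angular interval entirely covered
    by the union of intervals of strictly nearer neighbors.  Partially
    occluded neighbors are kept (with their full geometric ψ)."""
    infos = []
    for p in neighbors:
        disp = minimal_image(p.l - focal.l, env)
        d = float(np.hypot(*disp))
        infos.append((d, p, _angular_interval(disp, p.heading, p.h, p.w)))
    infos.sort(key=lambda t: (t[0], t[1].id))
    kept = []
    for d, p, (lo, hi) in infos:
        nearer = [iv for dd, _q, iv in infos if dd < d]
        if not _arc_covered(lo, hi, nearer):
            kept.append(p)
    kept.sort(key=lambda p: p.id)
    return kept


def observe(focal: AgentState, visible: Sequence[AgentState],
            previous_observation: Optional[dict[int, VisionTuple]] = None,
            env: Optional[EnvironmentConfig] = None,
            signed_theta: bool = False) -> list[VisionTuple]:
    """Compute γ for each visible (occlusion-filtered) neighbor.

    Derivatives are one-step backward differences against the previous
    observation of the same neighbor id; a newly sighted neighbor gets zero
    derivatives so the state space stays closed.
    """
    prev = previous_observation or {}
    out = []
    for p in visible:
        psi = subtended_angle(focal, p, env)
        theta = angular_position(focal, p, env, signed=signed_theta)
        disp = minimal_image(p.l - focal.l, env)
        d = float(np.hypot(*disp))
        old = prev.get(p.id)
        psi_dot = psi - old.psi if old is not None else 0.0
        theta_dot = theta - old.theta if old is not None else 0.0
        out.append(VisionTuple(psi=psi, psi_dot=psi_dot, theta=theta,
                               theta_dot=theta_dot, neighbor_id=p.id, distance=d))
    return out


def perceive(focal: AgentState, neighbors: Sequence[AgentState],
             previous_observation: Optional[dict[int, VisionTuple]] = None,
             env: Optional[EnvironmentConfig] = None,
             signed_theta: bool = False) -> list[VisionTuple]:
    """Full perception pipeline for one focal agent, vectorized over the
    in-range neighbors: subtended angles, bearings, occlusion filtering and
    temporal derivatives in one pass.

    Equivalent to ``occlusion_filter`` followed by ``observe`` (the per-pair
    reference path), but O(1) array operations per focal agent.
    """
    if len(neighbors) == 0:
        return []
    prev = previous_observation or {}
    m = len(neighbors)
    pos = np.array([p.l for p in neighbors])
    heads = np.array([p.heading for p in neighbors])
    hs = np.array([p.h for p in neighbors])
    ws = np.array([p.w for p in neighbors])
    disp = minimal_image(pos - focal.l[None, :], env)
    d = np.hypot(disp[:, 0], disp[:, 1])
    if np.any(d == 0):
        raise ValueError("focal and neighbor centers coincide")
    perp = np.stack([-heads[:, 1], heads[:, 0]], axis=1)
    signs_h = np.array([-1.0, 1.0, -1.0, 1.0])
    signs_w = np.array([1.0, 1.0, -1.0, -1.0])
    offs = (signs_h[None, :, None] * (hs[:, None, None] / 2) * heads[:, None, :]
            + signs_w[None, :, None] * (ws[:, None, None] / 2) * perp[:, None, :])
    chi = disp[:, None, :] + offs                        # (m, 4, 2)
    unit = chi / np.linalg.norm(chi, axis=2, keepdims=True)
    cosang = np.clip(np.einsum("mij,mij->mi", unit[:, _PAIR_I], unit[:, _PAIR_J]),
                     -1.0, 1.0)
    psi = np.arccos(np.min(cosang, axis=1))
    inside = ((np.abs(np.einsum("mi,mi->m", disp, heads)) <= hs / 2)
              & (np.abs(np.einsum("mi,mi->m", disp, perp)) <= ws / 2))
    psi[inside] = math.pi
    fhead = focal.heading
    theta = np.arccos(np.clip(disp @ fhead / d, -1.0, 1.0))
    if signed_theta:
        cross = fhead[0] * disp[:, 1] - fhead[1] * disp[:, 0]
        theta = np.where(cross < 0, -theta, theta)
    # angular intervals for occlusion
    bearings = np.arctan2(chi[:, :, 1], chi[:, :, 0])
    b0 = np.arctan2(disp[:, 1], disp[:, 0])
    offw = np.pi - np.mod(np.pi - (bearings - b0[:, None]), 2 * math.pi)
    lo = np.where(inside, -math.pi, b0 + offw.min(axis=1))
    hi = np.where(inside, math.pi, b0 + offw.max(axis=1))
    order = sorted(range(m), key=lambda j: (d[j], neighbors[j].id))
    out = []
    for rank, j in enumerate(order):
        nearer = [(lo[jj], hi[jj]) for jj in order[:rank] if d[jj] < d[j]]
        if _arc_covered(lo[j], hi[j], nearer):
            continue
        old = prev.get(neighbors[j].id)
        psi_dot = psi[j] - old.psi if old is not None else 0.0
        theta_dot = theta[j] - old.theta if old is not None else 0.0
        out.append(VisionTuple(psi=float(psi[j]), psi_dot=float(psi_dot),
                               theta=float(theta[j]), theta_dot=float(theta_dot),
                               neighbor_id=neighbors[j].id, distance=float(d[j])))
    out.sort(key=lambda o: o.neighbor_id)
    return out


def sentinel_bin(bin_width: float) -> int:
    """Bin index used for absent neighbor slots; guaranteed to lie outside the
    range of any real binned value (|angles| and clipped derivatives ≤ π)."""
    return int(math.floor(math.pi / bin_width)) + 2


def _bin(value: float, bin_width: float) -> int:
    return int(math.floor(value / bin_width + 1e-9))


def encode_state(observations: Sequence[VisionTuple], k: int,
                 bin_width: float) -> tuple[int, ...]:
    """Discretize observations into the fixed-length Q-table key.

    Slots are ordered by ascending θ (ties: ascending distance, then id),
    truncated to k, and each scalar floored to its bin index; derivatives are
    clipped to [−π, π] per step before binning.  Absent slots carry the
    sentinel bin.  The result is a hashable tuple of 4k integers.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    obs = sorted(observations, key=lambda o: (o.theta, o.distance, o.neighbor_id))
    if len(obs) > k:
        logger.debug("truncating %d observations to k=%d slots", len(obs), k)
        obs = obs[:k]
    sentinel = sentinel_bin(bin_width)
    slots: list[int] = []
    for o in obs:
        slots.append(_bin(o.psi, bin_width))
        slots.append(_bin(max(-math.pi, min(math.pi, o.psi_dot)), bin_width))
        slots.append(_bin(o.theta, bin_width))
        slots.append(_bin(max(-math.pi, min(math.pi, o.theta_dot)), bin_width))
    slots.extend([sentinel] * (4 * (k - len(obs))))
    return tuple(slots)
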