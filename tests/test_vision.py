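import math

import numpy as np
import pytest

from celswarm.vision import (AgentState, EnvironmentConfig, VisionTuple,
                             angular_position, corner_positions, encode_state,
                             local_environment, observe, occlusion_filter,
                             perceive, sentinel_bin, subtended_angle)
from conftest import boundary_span_oracle, make_agent


class TestCorners:
    def test_axis_aligned_heading(self):
        n = make_agent(l=(0, 0), v=(1, 0), h=0.07, w=0.01)
        rho = corner_positions(n).rho
        expected = {(0.035, 0.005), (0.035, -0.005), (-0.035, 0.005), (-0.035, -0.005)}
        got = {(round(x, 9), round(y, 9)) for x, y in rho}
        assert got == expected

    def test_heading_along_y_swaps_axes(self):
        n = make_agent(l=(1, 1), v=(0, 2), h=0.2, w=0.1)
        rho = corner_positions(n).rho
        got = {(round(x, 9), round(y, 9)) for x, y in rho}
        assert got == {(1.05, 1.1), (1.05, 0.9), (0.95, 1.1), (0.95, 0.9)}

    def test_centroid_is_center(self, rng):
        for _ in range(20):
            n = make_agent(l=rng.uniform(-2, 2, 2), v=rng.normal(size=2),
                           h=rng.uniform(0.01, 0.5), w=rng.uniform(0.01, 0.5))
            assert np.allclose(corner_positions(n).rho.mean(axis=0), n.l)

    def test_focal_frame_offsets(self):
        focal = make_agent(id=1, l=(0.5, 0.5))
        n = make_agent(id=2, l=(1, 1), v=(1, 0))
        cs = corner_positions(n, focal=focal)
        assert np.allclose(cs.chi, cs.rho - focal.l)


class TestSubtendedAngle:
    def test_square_neighbor_reference_value(self):
        # square body: the near-edge corners subtend the widest angle
        focal = make_agent(id=0, l=(0, 0), v=(1, 0))
        n = make_agent(id=1, l=(1, 0), v=(1, 0), h=0.1, w=0.1)
        psi = subtended_angle(focal, n)
        assert psi == pytest.approx(2 * math.atan(0.05 / 0.95), abs=1e-9)
        assert psi == pytest.approx(0.10517, abs=1e-4)

    def test_small_angle_halves_with_distance(self):
        focal = make_agent(id=0)
        near = make_agent(id=1, l=(2, 0), v=(0, 1), h=0.01, w=0.01)
        far = make_agent(id=2, l=(4, 0), v=(0, 1), h=0.01, w=0.01)
        ratio = subtended_angle(focal, near) / subtended_angle(focal, far)
        assert ratio == pytest.approx(2.0, rel=5e-3)

    def test_degenerate_point_neighbor(self):
        focal = make_agent(id=0)
        tiny = make_agent(id=1, l=(1, 1), v=(1, 1), h=1e-9, w=1e-9)
        assert subtended_angle(focal, tiny) < 1e-6

    def test_focal_inside_body_full_retina(self):
        focal = make_agent(id=0, l=(0.01, 0.0))
        big = make_agent(id=1, l=(0, 0), v=(1, 0), h=0.5, w=0.5)
        assert subtended_angle(focal, big) == math.pi

    def test_coincident_centers_error(self):
        a = make_agent(id=0)
        b = make_agent(id=1)
        with pytest.raises(ValueError):
            subtended_angle(a, b)

    def test_against_boundary_sampling_oracle(self, rng):
        """ψ agrees with a dense rectangle-boundary sampling oracle to 1e-3
        on random configurations."""
        for _ in range(200):
            focal = make_agent(id=0, l=rng.uniform(-1, 1, 2), v=rng.normal(size=2))
            n = make_agent(id=1, l=rng.uniform(-1, 1, 2), v=rng.normal(size=2),
                           h=rng.uniform(0.02, 0.3), w=rng.uniform(0.02, 0.3))
            d = np.linalg.norm(n.l - focal.l)
            if d < 0.5:  # keep the focal center safely outside the body
                n.l = focal.l + (n.l - focal.l) / max(d, 1e-9) * 0.5
            assert subtended_angle(focal, n) == pytest.approx(
                boundary_span_oracle(focal, n), abs=1e-3)


class TestAngularPosition:
    @pytest.mark.parametrize("loc,expected", [
        ((1, 0), 0.0), ((0, 1), math.pi / 2), ((-1, 0), math.pi),
    ])
    def test_cardinal_bearings(self, loc, expected):
        focal = make_agent(id=0, v=(0.1, 0))
        n = make_agent(id=1, l=loc)
        assert angular_position(focal, n) == pytest.approx(expected, abs=1e-12)

    def test_unsigned_left_right_symmetric(self):
        focal = make_agent(id=0, v=(0.1, 0))
        left = make_agent(id=1, l=(1, 1))
        right = make_agent(id=2, l=(1, -1))
        assert angular_position(focal, left) == pytest.approx(
            angular_position(focal, right))
        assert angular_position(focal, left, signed=True) == pytest.approx(
            -angular_position(focal, right, signed=True))

    def test_coincident_error(self):
        focal = make_agent(id=0)
        with pytest.raises(ValueError):
            angular_position(focal, make_agent(id=1))


class TestSceneInvariance:
    def test_translation_and_rotation_leave_psi_theta_unchanged(self, rng):
        for _ in range(50):
            focal = make_agent(id=0, l=rng.uniform(-1, 1, 2), v=rng.normal(size=2))
            n = make_agent(id=1, l=focal.l + rng.uniform(0.5, 2) *
                           np.array([math.cos(a := rng.uniform(0, 2 * math.pi)),
                                     math.sin(a)]),
                           v=rng.normal(size=2))
            psi0 = subtended_angle(focal, n)
            th0 = angular_position(focal, n)
            shift = rng.uniform(-5, 5, 2)
            ang = rng.uniform(0, 2 * math.pi)
            R = np.array([[math.cos(ang), -math.sin(ang)],
                          [math.sin(ang), math.cos(ang)]])
            f2 = make_agent(id=0, l=focal.l + shift, v=R @ focal.v)
            n2 = make_agent(id=1, l=focal.l + shift + R @ (n.l - focal.l), v=R @ n.v)
            assert subtended_angle(f2, n2) == pytest.approx(psi0, abs=1e-9)
            assert angular_position(f2, n2) == pytest.approx(th0, abs=1e-9)


class TestLocalEnvironment:
    def test_wraps_across_boundary(self, env):
        focal = make_agent(id=0, l=(0.1, 0.1), r=0.21)
        n = make_agent(id=1, l=(4.95, 0.1))
        assert local_environment(focal, [n], env) == [n]

    def test_strict_inequality_at_radius(self, env):
        focal = make_agent(id=0, l=(0, 0), r=0.21)
        at_r = make_agent(id=1, l=(0.21, 0))
        inside = make_agent(id=2, l=(0.2, 0))
        assert local_environment(focal, [at_r, inside], env) == [inside]

    def test_empty_population(self, env):
        assert local_environment(make_agent(id=0), [], env) == []


def _ray_visibility_oracle(focal, neighbors, n_rays=3600):
    """Discretized occlusion oracle: a neighbor is visible iff some ray
    bearing inside its angular interval is not inside the interval of any
    strictly nearer neighbor."""
    from celswarm.vision import _angular_interval
    rays = np.linspace(-math.pi, math.pi, n_rays, endpoint=False)

    def in_interval(bear, lo, hi):
        return np.mod(bear - lo, 2 * math.pi) <= (hi - lo) + 1e-12

    info = []
    for p in neighbors:
        disp = p.l - focal.l
        d = float(np.hypot(*disp))
        lo, hi = _angular_interval(disp, p.heading, p.h, p.w)
        info.append((d, p, lo, hi))
    visible = []
    for d, p, lo, hi in info:
        mine = in_interval(rays, lo, hi)
        covered = np.zeros_like(mine)
        for d2, _p2, lo2, hi2 in info:
            if d2 < d:
                covered |= in_interval(rays, lo2, hi2)
        if np.any(mine & ~covered):
            visible.append(p.id)
    return sorted(visible)


class TestOcclusion:
    def test_fully_hidden_behind_wider_neighbor(self):
        focal = make_agent(id=0, v=(0.1, 0))
        near = make_agent(id=1, l=(0.5, 0), v=(0, 1), h=0.2, w=0.2)
        far = make_agent(id=2, l=(1.0, 0), v=(0, 1), h=0.05, w=0.05)
        kept = occlusion_filter(focal, [near, far])
        assert [p.id for p in kept] == [1]

    def test_disjoint_bearings_both_kept(self):
        focal = make_agent(id=0, v=(0.1, 0))
        a = make_agent(id=1, l=(1, 0))
        b = make_agent(id=2, l=(0, 1))
        assert {p.id for p in occlusion_filter(focal, [a, b])} == {1, 2}

    def test_order_invariance(self, rng):
        focal = make_agent(id=0, v=(0.1, 0))
        nbrs = [make_agent(id=i + 1, l=rng.uniform(-0.2, 0.2, 2) + (0.3, 0),
                           v=rng.normal(size=2)) for i in range(5)]
        ref = {p.id for p in occlusion_filter(focal, nbrs)}
        for _ in range(5):
            perm = list(rng.permutation(5))
            assert {p.id for p in occlusion_filter(focal, [nbrs[i] for i in perm])} == ref

    def test_against_ray_casting_oracle(self, rng):
        for _ in range(40):
            focal = make_agent(id=0, v=(0.1, 0))
            nbrs = [make_agent(id=i + 1,
                               l=rng.uniform(0.1, 0.21) *
                               np.array([math.cos(a := rng.uniform(0, 2 * math.pi)),
                                         math.sin(a)]),
                               v=rng.normal(size=2)) for i in range(4)]
            kept = sorted(p.id for p in occlusion_filter(focal, nbrs))
            assert kept == _ray_visibility_oracle(focal, nbrs)


class TestObserve:
    def test_static_scene_zero_derivatives(self):
        focal = make_agent(id=0, v=(0.1, 0))
        n = make_agent(id=1, l=(0.1, 0), v=(0.1, 0))
        first = observe(focal, [n])
        second = observe(focal, [n], previous_observation={o.neighbor_id: o for o in first})
        assert second[0].psi_dot == 0.0 and second[0].theta_dot == 0.0

    def test_looming_neighbor_positive_psi_dot(self):
        focal = make_agent(id=0, l=(0, 0), v=(0.1, 0))
        n1 = make_agent(id=1, l=(0.2, 0), v=(-0.05, 0))
        first = observe(focal, [n1])
        n2 = make_agent(id=1, l=(0.15, 0), v=(-0.05, 0))
        second = observe(focal, [n2],
                         previous_observation={o.neighbor_id: o for o in first})
        assert second[0].psi_dot > 0
        assert second[0].theta_dot == pytest.approx(0.0, abs=1e-12)

    def test_derivatives_are_backward_differences(self, rng):
        focal1 = make_agent(id=0, l=(0, 0), v=(0.1, 0.02))
        focal2 = make_agent(id=0, l=(0.05, 0.01), v=(0.12, 0.01))
        na = make_agent(id=7, l=(0.3, 0.1), v=(0.05, -0.02))
        nb = make_agent(id=7, l=(0.28, 0.05), v=(0.05, -0.02))
        o1 = observe(focal1, [na])[0]
        o2 = observe(focal2, [nb], previous_observation={7: o1})[0]
        assert o2.psi_dot == pytest.approx(o2.psi - o1.psi, abs=1e-12)
        assert o2.theta_dot == pytest.approx(o2.theta - o1.theta, abs=1e-12)


class TestPerceivePipeline:
    def test_matches_reference_path(self, rng):
        """The vectorized pipeline equals occlusion_filter + observe."""
        for _ in range(30):
            focal = make_agent(id=0, l=rng.uniform(0, 5, 2), v=rng.normal(size=2) * 0.1)
            nbrs = [make_agent(id=i + 1,
                               l=focal.l + rng.uniform(0.02, 0.21) *
                               np.array([math.cos(a := rng.uniform(0, 2 * math.pi)),
                                         math.sin(a)]),
                               v=rng.normal(size=2) * 0.1) for i in range(6)]
            fast = perceive(focal, nbrs)
            ref = observe(focal, occlusion_filter(focal, nbrs))
            assert len(fast) == len(ref)
            for a, b in zip(sorted(fast, key=lambda o: o.neighbor_id),
                            sorted(ref, key=lambda o: o.neighbor_id)):
                assert a.neighbor_id == b.neighbor_id
                assert a.psi == pytest.approx(b.psi, abs=1e-10)
                assert a.theta == pytest.approx(b.theta, abs=1e-10)


class TestEncodeState:
    def test_alone_state_is_all_sentinel(self):
        enc = encode_state([], k=8, bin_width=0.01)
        assert enc == (sentinel_bin(0.01),) * 32

    def test_floor_binning(self):
        o = VisionTuple(psi=0.1049, psi_dot=0.0, theta=0.0, theta_dot=0.0,
                        neighbor_id=1, distance=1.0)
        enc = encode_state([o], k=1, bin_width=0.01)
        assert enc[0] == 10

    def test_sentinel_never_collides_with_real_bins(self):
        for bw in (0.01, 0.05, 0.001):
            sent = sentinel_bin(bw)
            assert sent > math.floor(math.pi / bw)

    def test_deterministic_and_truncating(self, rng):
        obs = [VisionTuple(psi=rng.uniform(0, 3), psi_dot=rng.normal(),
                           theta=rng.uniform(0, 3), theta_dot=rng.normal(),
                           neighbor_id=i, distance=rng.uniform(0.01, 0.2))
               for i in range(10)]
        e1 = encode_state(obs, k=8, bin_width=0.01)
        e2 = encode_state(list(obs), k=8, bin_width=0.01)
        assert e1 == e2
        assert len(e1) == 32
        # slots follow ascending theta
        thetas = sorted(o.theta for o in obs)[:8]
        assert [e1[4 * i + 2] for i in range(8)] == \
            [math.floor(t / 0.01 + 1e-9) for t in thetas]

    def test_derivative_clipping(self):
        o = VisionTuple(psi=0.1, psi_dot=10.0, theta=0.1, theta_dot=-10.0,
                        neighbor_id=1, distance=0.1)
        enc = encode_state([o], k=1, bin_width=0.01)
        assert enc[1] == math.floor(math.pi / 0.01 + 1e-9)
        assert enc[3] == math.floor(-math.pi / 0.01 + 1e-9)
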