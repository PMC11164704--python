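import math

import numpy as np
import pandas as pd
import pytest

from thermosoar import (
    ActionDelta,
    EpisodeConfig,
    NoiseConfig,
    ThermalSoaringEnv,
    compute_theta,
    observe,
)
from thermosoar.environment import (
    NORMALIZATION_RANGES,
    OBS_VARIABLES,
    normalize_observation,
)


def rot(v, deg):
    a = math.radians(deg)
    return np.array(
        [v[0] * math.cos(a) - v[1] * math.sin(a),
         v[0] * math.sin(a) + v[1] * math.cos(a)]
    )


class TestComputeTheta:
    WIND = np.array([1.0, 0.0])

    def test_headwind_is_zero(self):
        assert compute_theta(np.array([-12.0, 0.0]), self.WIND, -1) == 0.0
        assert compute_theta(np.array([-12.0, 0.0]), self.WIND, +1) == 0.0

    def test_tailwind_is_180(self):
        assert abs(compute_theta(np.array([5.0, 0.0]), self.WIND, -1)) == 180.0

    def test_clockwise_circle_increases_through_headwind_to_tailwind(self):
        # clockwise in +x wind: heading angle chi decreases with time
        thetas = []
        for chi_deg in np.arange(180.0, -0.5, -15.0):  # headwind -> tailwind
            v = np.array([math.cos(math.radians(chi_deg)),
                          math.sin(math.radians(chi_deg))]) * 14.0
            thetas.append(compute_theta(v, self.WIND, -1))
        assert thetas[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(thetas) > 0)
        assert thetas[-1] == pytest.approx(180.0)

    def test_counterclockwise_mirrored(self):
        v = np.array([0.0, 9.0])  # crosswind
        cw = compute_theta(v, self.WIND, -1)
        ccw = compute_theta(v, self.WIND, +1)
        assert cw == pytest.approx(-ccw)

    def test_invariant_under_scene_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.normal(size=2) * 10
            ang = rng.uniform(0, 360)
            for sense in (-1, 1):
                t0 = compute_theta(v, self.WIND, sense)
                t1 = compute_theta(rot(v, ang), rot(self.WIND, ang), sense)
                assert t1 == pytest.approx(t0, abs=1e-9)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError):
            compute_theta(np.zeros(2), self.WIND, 1)


class TestObserve:
    def frame(self, **over):
        f = {"V": 15.0, "vz": 0.0, "sigma": 0.0, "alpha": 0.0,
             "theta": 0.0, "u": 5.0}
        f.update(over)
        return f

    def test_midpoint_maps_to_zero(self):
        obs = observe([self.frame()], memory_size=0)
        assert obs == pytest.approx(np.zeros(6))

    def test_range_limits_map_to_unit(self):
        lo = {v: NORMALIZATION_RANGES[v][0] for v in OBS_VARIABLES}
        hi = {v: NORMALIZATION_RANGES[v][1] for v in OBS_VARIABLES}
        assert observe([lo], 0) == pytest.approx(-np.ones(6))
        assert observe([hi], 0) == pytest.approx(np.ones(6))

    def test_out_of_range_clipped(self):
        obs = observe([self.frame(V=99.0, vz=-99.0)], 0)
        assert obs[0] == 1.0 and obs[1] == -1.0

    def test_front_padding_repeats_initial_frame(self):
        h = [self.frame(V=10.0), self.frame(V=20.0)]
        obs = observe(h, memory_size=3)
        v_cols = obs[0::6]
        assert v_cols[0] == v_cols[1] == v_cols[2]  # padded with V=10
        assert v_cols[3] == normalize_observation("V", 20.0)

    @pytest.mark.parametrize("B", range(1, 10))
    def test_length_and_bounds_for_all_buffer_sizes(self, B):
        env = ThermalSoaringEnv(EpisodeConfig(memory_size=B, u_min=1.0,
                                              u_max=3.0, seed=0))
        obs = env.reset(seed=42)
        for _ in range(12):
            assert len(obs) == 6 * (B + 1)
            assert np.all(obs >= -1.0) and np.all(obs <= 1.0)
            obs, _, done, _ = env.step((3.0, 0.5))
            if done:
                break

    def test_deterministic_without_noise(self):
        h = [self.frame(), self.frame(V=18.0)]
        assert np.array_equal(observe(h, 2), observe(h, 2))


class TestReset:
    def test_same_seed_same_state(self):
        env = ThermalSoaringEnv(EpisodeConfig(u_min=0.0, u_max=5.0))
        env.reset(seed=9)
        s1, u1 = env.state, env.u
        env.reset(seed=9)
        assert env.state == s1 and env.u == u1

    def test_initial_annulus_and_kinematics(self):
        env = ThermalSoaringEnv(EpisodeConfig(u_min=0.0, u_max=6.0))
        dists, winds = [], []
        for i in range(500):
            env.reset(seed=i)
            dists.append(math.hypot(env.state.x, env.state.y))
            winds.append(env.u)
            assert env.state.z == 500.0 and env.state.V == 15.0
        assert min(dists) >= 80.0 and max(dists) <= 150.0
        assert 0.0 <= min(winds) and max(winds) <= 6.0
        # initial climb rate V sin(-5 deg)
        assert env.state.vz == pytest.approx(15.0 * math.sin(math.radians(-5.0)))


class TestStep:
    def test_action_clipped_to_limits(self):
        env = ThermalSoaringEnv(EpisodeConfig(seed=0))
        env.reset(seed=1)
        env.step((20.0, 0.0))  # requests +20, applies +15
        assert env.ctrl.sigma == 15.0

    def test_bank_saturates_at_50(self):
        env = ThermalSoaringEnv(EpisodeConfig(seed=0))
        env.reset(seed=1)
        for _ in range(5):
            env.step((15.0, 0.0))
        assert env.ctrl.sigma == 50.0
        env.step((15.0, 0.0))
        assert env.ctrl.sigma == 50.0

    def test_alpha_saturates_at_30(self):
        env = ThermalSoaringEnv(EpisodeConfig(seed=0))
        env.reset(seed=1)
        for _ in range(4):
            env.step((0.0, 10.0))
        assert env.ctrl.alpha == 30.0

    def test_p_center_is_distance_over_50(self):
        env = ThermalSoaringEnv(EpisodeConfig(seed=0))
        env.reset(seed=1)
        _, r, _, info = env.step((0.0, 0.0))
        assert r.p_center == pytest.approx(-info["d_center"] / 50.0)

    def test_timeout_after_200_steps_and_return_accounting(self):
        env = ThermalSoaringEnv(EpisodeConfig(u_min=1.0, u_max=1.0, seed=0))
        env.reset(seed=3)
        total, n, done = 0.0, 0, False
        while not done:
            _, r, done, info = env.step((2.0, 0.0))
            total += r.total
            n += 1
        assert n == 200 and not info["crashed"] and not info["unstable"]
        traj = env.trajectory()
        # independent accounting from the logged trajectory
        dz = traj["z"].iloc[-1] - traj["z"].iloc[0]
        d = np.hypot(traj["x"] - env.u * traj["t"], traj["y"])
        expected = dz - d.iloc[1:].sum() / 50.0
        assert total == pytest.approx(expected, rel=1e-9)

    def test_step_after_done_rejected(self):
        env = ThermalSoaringEnv(EpisodeConfig(duration=2.0, seed=0))
        env.reset(seed=1)
        env.step((0.0, 0.0))
        _, _, done, _ = env.step((0.0, 0.0))
        assert done
        with pytest.raises(RuntimeError):
            env.step((0.0, 0.0))

    def test_instability_penalty_counts_remaining_seconds(self):
        # full nose-down dive goes unstable; P_stab = -(200 - t_end)
        env = ThermalSoaringEnv(EpisodeConfig(seed=0))
        env.reset(seed=5)
        done = False
        while not done:
            _, r, done, info = env.step((0.0, -10.0))
        assert info["unstable"]
        assert r.p_stab == pytest.approx(-(200.0 - env.step_count))
        assert r.p_stab < -100.0  # the dive fails early in the episode

    def test_episode_bit_reproducible(self):
        cfg = EpisodeConfig(u_min=0.0, u_max=4.0, gust_std=0.5, seed=0)
        rows = []
        for _ in range(2):
            env = ThermalSoaringEnv(cfg)
            env.reset(seed=11)
            for k in range(40):
                _, _, done, _ = env.step(((-1) ** k * 5.0, 1.0))
                if done:
                    break
            rows.append(env.trajectory())
        pd.testing.assert_frame_equal(rows[0], rows[1])


class TestSensorNoise:
    def test_noise_perturbs_observation(self):
        noisy = EpisodeConfig(noise=NoiseConfig(levels={"V": 0.5}), seed=0)
        env1 = ThermalSoaringEnv(noisy)
        env2 = ThermalSoaringEnv(EpisodeConfig(seed=0))
        o1, o2 = env1.reset(seed=2), env2.reset(seed=2)
        assert not np.allclose(o1[0::6], o2[0::6])
        assert np.allclose(o1[4::6], o2[4::6])  # theta untouched

    def test_memory_replays_the_same_noisy_reading(self):
        cfg = EpisodeConfig(noise=NoiseConfig(levels={"V": 1.0}), seed=0)
        env = ThermalSoaringEnv(cfg)
        env.reset(seed=4)
        o1, _, _, _ = env.step((0.0, 0.0))
        o2, _, _, _ = env.step((0.0, 0.0))
        # the V entry observed at step 1 reappears one slot earlier at step 2
        assert o2[-12] == o1[-6]


def test_reward_terms_sum():
    from thermosoar import RewardTerms

    r = RewardTerms(vz_term=1.0, p_center=-1.0, p_stab=-50.0,
                    crash_penalty=0.0)
    assert r.total == -50.0


def test_episode_config_validation():
    with pytest.raises(ValueError):
        EpisodeConfig(duration=200.0, control_interval=3.0)
    with pytest.raises(ValueError):
        EpisodeConfig(u_min=4.0, u_max=2.0)
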