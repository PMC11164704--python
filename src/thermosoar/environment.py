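"""Episodic thermal-soaring environment.

A glider is dropped near (but outside) a drifting thermal at z = 500 m and
has 200 s to find and exploit it.  Every control second the agent observes
a normalized vector of {V, v_z, sigma, alpha, theta, u} — current values
plus a memory buffer of the previous B control steps — and commands
increments (d_sigma, d_alpha) of its bank angle and angle-of-attack.  The
per-step reward is the climb rate plus a shaping penalty proportional to
the distance from the thermal center; going unstable costs one point per
remaining second and ends the episode; hitting the ground costs 1000.

The environment exposes a plain ``reset(seed=...)`` / ``step(action)``
episodic-control API and logs a 1 Hz trajectory table per episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .atmosphere import (
    GustSeries,
    ThermalParams,
    WindConfig,
    wind_vector,
)
from .flight_dynamics import (
    ControlState,
    GliderParams,
    GliderState,
    InstabilityError,
    PHYSICS_DT,
    PitchMonitor,
    _rk4_tuple,
    vulture_params,
)

__all__ = [
    "OBS_VARIABLES",
    "NORMALIZATION_RANGES",
    "SENSOR_REFERENCE_STD",
    "ActionDelta",
    "RewardTerms",
    "NoiseConfig",
    "EpisodeConfig",
    "compute_theta",
    "normalize_observation",
    "ThermalSoaringEnv",
]

OBS_VARIABLES = ("V", "vz", "sigma", "alpha", "theta", "u")

#: Physical ranges mapped affinely onto [-1, 1].
NORMALIZATION_RANGES: dict[str, tuple[float, float]] = {
    "V": (0.0, 30.0),  # m/s
    "vz": (-5.0, 5.0),  # m/s
    "sigma": (-50.0, 50.0),  # deg
    "alpha": (-30.0, 30.0),  # deg
    "theta": (-180.0, 180.0),  # deg
    "u": (0.0, 10.0),  # m/s
}

#: Trajectory-scale standard deviations used to express sensor-noise levels
#: relative to each variable's typical variation during soaring.
SENSOR_REFERENCE_STD: dict[str, float] = {
    "V": 2.3,  # m/s
    "vz": 2.6,  # m/s
    "theta": 116.4,  # deg
    "sigma": 11.9,  # deg
    "alpha": 5.9,  # deg
    "u": 1.0,  # m/s; u-sensor noise is specified in absolute m/s
}

D_SIGMA_LIMIT = 15.0  # deg per control step
D_ALPHA_LIMIT = 10.0  # deg per control step
CRASH_PENALTY = -1000.0
P_CENTER_SCALE = 50.0  # m per penalty unit


@dataclass(frozen=True)
class ActionDelta:
    """Per-control-step increments, degrees."""

    d_sigma: float
    d_alpha: float

    def clipped(self) -> "ActionDelta":
        return ActionDelta(
            d_sigma=min(max(self.d_sigma, -D_SIGMA_LIMIT), D_SIGMA_LIMIT),
            d_alpha=min(max(self.d_alpha, -D_ALPHA_LIMIT), D_ALPHA_LIMIT),
        )


@dataclass(frozen=True)
class RewardTerms:
    """Additive reward decomposition for one control step."""

    vz_term: float = 0.0
    p_center: float = 0.0
    p_stab: float = 0.0
    crash_penalty: float = 0.0

    @property
    def total(self) -> float:
        return self.vz_term + self.p_center + self.p_stab + self.crash_penalty


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian sensor noise, injected in physical units before
    normalization.

    ``levels`` maps a variable name to its noise std expressed relative to
    ``SENSOR_REFERENCE_STD`` (for "u": absolute m/s).  Empty dict = no
    noise.
    """

    levels: dict[str, float] = field(default_factory=dict)

    def std_for(self, var: str) -> float:
        lvl = self.levels.get(var, 0.0)
        return lvl * SENSOR_REFERENCE_STD[var]

    @property
    def enabled(self) -> bool:
        return any(v > 0 for v in self.levels.values())


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode layout and randomized initial conditions."""

    duration: float = 200.0  # s
    control_interval: float = 1.0  # s
    memory_size: int = 8  # previous control steps kept in the observation
    z0: float = 500.0  # m
    V0: float = 15.0  # m/s
    gamma0_deg: float = -5.0
    u_min: float = 0.0  # m/s
    u_max: float = 0.0  # m/s
    init_radius: tuple[float, float] = (80.0, 150.0)  # m annulus
    gust_std: float = 0.0  # m/s
    gust_period: float = 20.0  # s
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = self.duration / self.control_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be divisible by control_interval")
        if not 0 <= self.u_min <= self.u_max:
            raise ValueError("require 0 <= u_min <= u_max")
        if self.memory_size < 0:
            raise ValueError("memory_size must be >= 0")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.control_interval)


def compute_theta(
    velocity_xy: np.ndarray,
    wind_direction: np.ndarray,
    rotation_sense: int,
) -> float:
    """Signed angle from the wind, degrees in (-180, 180].

    0 means flying into the wind (headwind), +-180 flying with it
    (tailwind).  ``rotation_sense`` is +1 for counter-clockwise circling
    (viewed from above) and -1 for clockwise; the sign convention is
    mirrored so that theta always increases through the
    headwind -> tailwind half of the circle.
    """
    vx, vy = float(velocity_xy[0]), float(velocity_xy[1])
    if vx == 0.0 and vy == 0.0:
        raise ValueError("theta undefined for zero horizontal velocity")
    wx, wy = float(wind_direction[0]), float(wind_direction[1])
    nrm = math.hypot(wx, wy)
    if nrm == 0:
        raise ValueError("wind direction must be a nonzero vector")
    upx, upy = -wx / nrm, -wy / nrm  # upwind unit vector
    phi = math.degrees(math.atan2(upx * vy - upy * vx, upx * vx + upy * vy))
    theta = rotation_sense * phi
    if theta <= -180.0:
        theta += 360.0
    elif theta > 180.0:
        theta -= 360.0
    return theta


def normalize_observation(var: str, value: float) -> float:
    """Affine map of a physical value onto [-1, 1], clipped."""
    lo, hi = NORMALIZATION_RANGES[var]
    return min(max(2.0 * (value - lo) / (hi - lo) - 1.0, -1.0), 1.0)


def observe(
    history: list[dict[str, float]],
    memory_size: int,
    noise: Optional[NoiseConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Build the normalized observation vector from raw state frames.

    ``history`` holds one dict per past control step (oldest first,
    current last) with keys ``OBS_VARIABLES`` in physical units.  The
    buffer is front-padded by repeating the earliest frame when the episode
    is younger than the memory.  Optional Gaussian sensor noise is applied
    per variable in physical units, then each entry is normalized and
    clipped.  Layout: frames ordered oldest -> current, each frame in
    ``OBS_VARIABLES`` order; length = 6 * (memory_size + 1).
    """
    if not history:
        raise ValueError("history must be non-empty")
    frames = history[-(memory_size + 1):]
    frames = [frames[0]] * (memory_size + 1 - len(frames)) + frames
    out = np.empty(6 * (memory_size + 1))
    k = 0
    for frame in frames:
        for var in OBS_VARIABLES:
            val = frame[var]
            if noise is not None and noise.enabled:
                std = noise.std_for(var)
                if std > 0:
                    if rng is None:
                        raise ValueError("sensor noise requires an rng")
                    val += rng.normal(0.0, std)
            out[k] = normalize_observation(var, val)
            k += 1
    return out


class ThermalSoaringEnv:
    """Plain episodic-control environment (reset / step / seed).

    ``reset`` returns the first observation; ``step`` returns
    ``(observation, reward_terms, done, info)``.  A 1 Hz trajectory table
    for the running episode accumulates in ``trajectory_rows`` and can be
    retrieved with :meth:`trajectory`.
    """

    #: action box, degrees per step
    action_low = np.array([-D_SIGMA_LIMIT, -D_ALPHA_LIMIT])
    action_high = np.array([D_SIGMA_LIMIT, D_ALPHA_LIMIT])

    def __init__(
        self,
        config: Optional[EpisodeConfig] = None,
        glider: Optional[GliderParams] = None,
        thermal: Optional[ThermalParams] = None,
        reward_stability: bool = True,
        reward_center: bool = True,
    ):
        self.config = config if config is not None else EpisodeConfig()
        self.glider = glider if glider is not None else vulture_params()
        self.thermal = thermal if thermal is not None else ThermalParams()
        self.reward_stability = reward_stability
        self.reward_center = reward_center
        self._rng = np.random.default_rng(self.config.seed)
        self._active = False

    @property
    def observation_size(self) -> int:
        return 6 * (self.config.memory_size + 1)

    def seed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    # -- episode bookkeeping -------------------------------------------------

    def reset(self, seed: Optional[int] = None) -> np.ndarray:
        if seed is not None:
            self.seed(seed)
        cfg = self.config
        r = self._rng
        heading = r.uniform(0.0, 2.0 * math.pi)
        ring_phi = r.uniform(0.0, 2.0 * math.pi)
        ring_rad = r.uniform(*cfg.init_radius)
        self.u = float(r.uniform(cfg.u_min, cfg.u_max))
        self.wind = WindConfig(
            u=self.u, gust_std=cfg.gust_std, gust_period=cfg.gust_period
        )
        gust_rng = np.random.default_rng(r.integers(0, 2**31 - 1))
        self._gusts = (
            GustSeries(self.wind, gust_rng) if cfg.gust_std > 0 else None
        )
        self.state = GliderState(
            x=ring_rad * math.cos(ring_phi),
            y=ring_rad * math.sin(ring_phi),
            z=cfg.z0,
            V=cfg.V0,
            gamma=math.radians(cfg.gamma0_deg),
            chi=heading,
        )
        self.ctrl = ControlState(sigma=0.0, alpha=6.0, beta=0.0)
        self.t = 0.0
        self.step_count = 0
        self._pitch = PitchMonitor(self.state.gamma)
        self._chi_hist = [self.state.chi]
        self._rotation_sense = 1
        self._theta = self._compute_theta_now()
        self._history = [self._sensor_frame()]
        self.trajectory_rows: list[dict] = []
        self._active = True
        self._log_row(action=(0.0, 0.0), reward=RewardTerms())
        return observe(self._history, cfg.memory_size)

    def _wind_field(self, x, y, z, t):
        # integrator substeps may probe below ground just before a crash is
        # detected; the field query must stay valid there
        return wind_vector(x, y, max(z, 1e-6), t, self.wind, self.thermal,
                           self._gusts)

    def _air_now(self):
        return self._wind_field(self.state.x, self.state.y, self.state.z,
                                self.t)

    def _compute_theta_now(self) -> float:
        # theta is defined on the ground-frame velocity (what a GPS track
        # or the bird's motion over ground shows)
        vx, vy, _ = self.state.ground_velocity(self._air_now())
        # rotation sense from the recent mean heading rate (5 s window)
        hist = self._chi_hist[-6:]
        if len(hist) >= 2:
            un = np.unwrap(hist)
            d = un[-1] - un[0]
            if d != 0.0:
                self._rotation_sense = 1 if d > 0 else -1
        try:
            return compute_theta(
                np.array([vx, vy]), np.array([1.0, 0.0]), self._rotation_sense
            )
        except ValueError:  # zero horizontal velocity: hold previous value
            return getattr(self, "_theta", 0.0)

    def _current_u(self) -> float:
        return self._gusts.u_at(self.t) if self._gusts is not None else self.u

    def _frame(self) -> dict[str, float]:
        gvx, gvy, gvz = self.state.ground_velocity(self._air_now())
        return {
            "V": math.sqrt(gvx * gvx + gvy * gvy + gvz * gvz),
            "vz": gvz,
            "sigma": self.ctrl.sigma,
            "alpha": self.ctrl.alpha,
            "theta": self._theta,
            "u": self._current_u(),
        }

    def _sensor_frame(self) -> dict[str, float]:
        """One measurement: noise is drawn once here, so the memory buffer
        replays the same noisy reading at later steps."""
        frame = self._frame()
        noise = self.config.noise
        if noise.enabled:
            for var in OBS_VARIABLES:
                std = noise.std_for(var)
                if std > 0:
                    frame[var] += float(self._rng.normal(0.0, std))
        return frame

    def _distance_to_center(self) -> float:
        return math.hypot(self.state.x - self.u * self.t, self.state.y)

    def _log_row(self, action, reward: RewardTerms) -> None:
        gvx, gvy, gvz = self.state.ground_velocity(self._air_now())
        self.trajectory_rows.append(
            {
                "t": self.t,
                "x": self.state.x,
                "y": self.state.y,
                "z": self.state.z,
                "V": math.sqrt(gvx * gvx + gvy * gvy + gvz * gvz),
                "vz": gvz,
                "sigma": self.ctrl.sigma,
                "alpha": self.ctrl.alpha,
                "theta": self._theta,
                "u": self._current_u(),
                "d_center": self._distance_to_center(),
                "reward_vz": reward.vz_term,
                "reward_pcenter": reward.p_center,
                "action_dsigma": action[0],
                "action_dalpha": action[1],
            }
        )

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory_rows)

    # -- dynamics ------------------------------------------------------------

    def step(
        self, action
    ) -> tuple[np.ndarray, RewardTerms, bool, dict]:
        if not self._active:
            raise RuntimeError("episode finished; call reset() first")
        cfg = self.config
        if isinstance(action, ActionDelta):
            act = action.clipped()
        else:
            act = ActionDelta(float(action[0]), float(action[1])).clipped()
        self.ctrl = ControlState(
            sigma=self.ctrl.sigma + act.d_sigma,
            alpha=self.ctrl.alpha + act.d_alpha,
            beta=self.ctrl.beta,
        ).clipped()

        z_before = self.state.z
        crashed = unstable = False
        n_sub = max(1, round(cfg.control_interval / PHYSICS_DT))
        h = cfg.control_interval / n_sub
        s = (self.state.x, self.state.y, self.state.z,
             self.state.V, self.state.gamma, self.state.chi)
        for _ in range(n_sub):
            try:
                s = _rk4_tuple(
                    s, self.ctrl, self._wind_field, self.t, h, self.glider
                )
            except InstabilityError:
                unstable = True
                break
            self.t += h
            if self._pitch.update(s[4]):
                unstable = True
                break
            if s[2] <= 0.0:
                crashed = True
                break
        self.state = GliderState(*s)
        if not (crashed or unstable):
            # land exactly on the control grid despite float accumulation
            self.t = round(self.t / cfg.control_interval) * cfg.control_interval
        self.step_count += 1
        self._chi_hist.append(self.state.chi)
        self._theta = self._compute_theta_now()

        vz_term = (self.state.z - z_before) / cfg.control_interval
        d = self._distance_to_center()
        p_center = -d / P_CENTER_SCALE if self.reward_center else 0.0
        p_stab = 0.0
        crash_pen = 0.0
        done = False
        if crashed:
            crash_pen = CRASH_PENALTY
            done = True
        elif unstable:
            if self.reward_stability:
                p_stab = -(cfg.duration - self.step_count * cfg.control_interval)
            done = True
        elif self.step_count >= cfg.n_steps:
            done = True
        reward = RewardTerms(
            vz_term=vz_term,
            p_center=p_center,
            p_stab=p_stab,
            crash_penalty=crash_pen,
        )
        self._history.append(self._sensor_frame())
        self._log_row(action=(act.d_sigma, act.d_alpha), reward=reward)
        obs = observe(self._history, cfg.memory_size)
        info = {
            "t": self.t,
            "d_center": d,
            "crashed": crashed,
            "unstable": unstable,
            "u": self.u,
        }
        if done:
            self._active = False
        return obs, reward, done, info
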