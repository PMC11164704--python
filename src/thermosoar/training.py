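"""Curriculum training of a deterministic actor-critic soaring agent.

The learner is a compact, self-contained DDPG (deep deterministic policy
gradient): a deterministic actor maps the normalized observation to the
two control increments, a critic estimates the action-value Q(s, a), both
are two-hidden-layer (200 + 200, ReLU) fully-connected networks trained
from a replay buffer with target networks, Polyak averaging and Adam.
Everything is plain numpy with hand-written backpropagation — the networks
are small enough that this is fast and keeps the whole learning stack
inspectable (the activation analysis in :mod:`thermosoar.nn_inspection`
reads the very arrays trained here).

Curriculum learning wraps the learner: the horizontal-wind range of the
episode sampler widens stage by stage (nominally 0-2, 0-4, 0-6 m/s) while
the network weights carry over, and checkpoints tagged by cumulative
simulated-flight time are emitted for later inspection ("young" /
"intermediate" / "expert" snapshots).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atmosphere import ThermalParams
from .environment import (
    D_ALPHA_LIMIT,
    D_SIGMA_LIMIT,
    EpisodeConfig,
    ThermalSoaringEnv,
)
from .flight_dynamics import GliderParams, vulture_params
from .metrics import (
    EfficiencyBounds,
    PerformanceSummary,
    efficiency_eta,
    fraction_in_thermal,
    optimal_climb_rate,
    baseline_climb_rate,
)

__all__ = [
    "MLP",
    "DDPGConfig",
    "DDPGAgent",
    "AgentSpec",
    "CurriculumStage",
    "CurriculumSchedule",
    "TrainingResult",
    "curriculum_train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "replay_observations",
]

ACTION_SCALE = np.array([D_SIGMA_LIMIT, D_ALPHA_LIMIT])


# ---------------------------------------------------------------------------
# Minimal feed-forward network with hand-written backprop


class MLP:
    """Fully connected ReLU network with linear or tanh output.

    Weights are kept as a flat list of (W, b) pairs; gradients are
    computed by explicit backpropagation.  He initialization for hidden
    layers, small uniform for the output layer (the usual choice for
    deterministic-policy heads so initial actions are near zero).
    """

    def __init__(
        self,
        sizes: Sequence[int],
        out: str = "linear",
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.sizes = list(sizes)
        self.out = out
        self.W = []
        self.b = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            if last:
                lim = 3e-3
                w = rng.uniform(-lim, lim, size=(n_in, n_out))
            else:
                w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
            self.W.append(w)
            self.b.append(np.zeros(n_out))

    def forward(self, x: np.ndarray, keep: bool = False):
        """Batch forward pass; with ``keep`` returns hidden activations."""
        h = np.atleast_2d(x)
        hidden = []
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
                hidden.append(h)
        if self.out == "tanh":
            h = np.tanh(h)
        return (h, hidden) if keep else h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def forward_cache(self, x: np.ndarray):
        """Forward pass returning the output and a cache for backward."""
        h = np.atleast_2d(x)
        acts = [h]
        pre_relu = []
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i < len(self.W) - 1:
                pre_relu.append(h)
                h = np.maximum(h, 0.0)
            acts.append(h)
        y = np.tanh(acts[-1]) if self.out == "tanh" else acts[-1]
        return y, (acts, pre_relu, y)

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of sum(grad_out * output) w.r.t. weights and input."""
        acts, pre_relu, y = cache
        if self.out == "tanh":
            delta = grad_out * (1.0 - y * y)
        else:
            delta = grad_out.copy()
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in reversed(range(len(self.W))):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
            if i > 0:
                delta = delta * (pre_relu[i - 1] > 0)
        return gW, gb, delta  # delta: gradient w.r.t. the input

    def forward_backward(self, x: np.ndarray, grad_out: np.ndarray):
        """One-shot forward + backward (see :meth:`backward`)."""
        _, cache = self.forward_cache(x)
        return self.backward(cache, grad_out)

    def params(self):
        return self.W + self.b

    def copy(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.sizes = list(self.sizes)
        other.out = self.out
        other.W = [w.copy() for w in self.W]
        other.b = [b.copy() for b in self.b]
        return other


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Agent


@dataclass(frozen=True)
class AgentSpec:
    """Network layout: two hidden layers of 200 units for actor and critic."""

    obs_dim: int = 54  # 6 variables x (8 previous + current)
    action_dim: int = 2
    hidden: tuple[int, ...] = (200, 200)


@dataclass
class DDPGConfig:
    """Learner hyper-parameters (library-style defaults)."""

    buffer_size: int = 200_000
    batch_size: int = 64
    gamma: float = 0.99
    actor_lr: float = 1e-4
    critic_lr: float = 1e-3
    tau: float = 0.005  # Polyak averaging rate
    exploration_std: float = 0.15  # fraction of the action scale
    noise_type: str = "ou"  # "ou" (temporally correlated) or "gaussian"
    ou_theta: float = 0.15  # mean-reversion rate of the OU noise, 1/step
    warmup_steps: int = 1_000  # uniform-random actions before learning
    update_every: int = 1  # gradient updates per environment step
    reward_scale: float = 0.05  # scales rewards fed to the critic
    hidden: tuple[int, ...] = (200, 200)


class ReplayBuffer:
    def __init__(self, capacity: int, obs_dim: int, act_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.act = np.zeros((capacity, act_dim), dtype=np.float32)
        self.rew = np.zeros(capacity, dtype=np.float32)
        self.nxt = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.done = np.zeros(capacity, dtype=np.float32)
        self.size = 0
        self.ptr = 0

    def add(self, o, a, r, o2, d) -> None:
        i = self.ptr
        self.obs[i] = o
        self.act[i] = a
        self.rew[i] = r
        self.nxt[i] = o2
        self.done[i] = d
        self.ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, n: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, size=n)
        return (
            self.obs[idx], self.act[idx], self.rew[idx],
            self.nxt[idx], self.done[idx],
        )


class DDPGAgent:
    """Deterministic actor-critic with target networks.

    The actor outputs actions in normalized units [-1, 1]^2, scaled to
    degrees by ``ACTION_SCALE``; the critic takes (observation,
    normalized action).
    """

    def __init__(
        self,
        spec: AgentSpec = AgentSpec(),
        config: DDPGConfig = DDPGConfig(),
        seed: int = 0,
    ):
        self.spec = spec
        self.config = config
        rng = np.random.default_rng(seed)
        h = list(config.hidden)
        self.actor = MLP([spec.obs_dim, *h, spec.action_dim], out="tanh", rng=rng)
        self.critic = MLP([spec.obs_dim + spec.action_dim, *h, 1], rng=rng)
        self.target_actor = self.actor.copy()
        self.target_critic = self.critic.copy()
        self.opt_actor = Adam(self.actor.params(), config.actor_lr)
        self.opt_critic = Adam(self.critic.params(), config.critic_lr)
        self.buffer = ReplayBuffer(
            config.buffer_size, spec.obs_dim, spec.action_dim
        )
        self.rng = rng
        self.total_env_steps = 0
        self._ou_state = np.zeros(spec.action_dim)

    # -- acting ------------------------------------------------------------

    def reset_noise(self) -> None:
        self._ou_state = np.zeros(self.spec.action_dim)

    def _noise(self) -> np.ndarray:
        cfg = self.config
        if cfg.noise_type == "gaussian":
            return self.rng.normal(0.0, cfg.exploration_std,
                                   size=self.spec.action_dim)
        # Ornstein-Uhlenbeck: temporally correlated, better at sustained
        # maneuvers (e.g. holding a turn long enough to feel the updraft)
        self._ou_state += (
            -cfg.ou_theta * self._ou_state
            + self.rng.normal(0.0, cfg.exploration_std,
                              size=self.spec.action_dim)
        )
        return self._ou_state

    def act(self, obs: np.ndarray, explore: bool = False) -> np.ndarray:
        """Action in degrees; optionally with exploration noise."""
        a = self.actor(obs[None, :])[0]
        if explore:
            a = a + self._noise()
        return np.clip(a, -1.0, 1.0) * ACTION_SCALE

    def random_action(self) -> np.ndarray:
        return self.rng.uniform(-1.0, 1.0, size=self.spec.action_dim) * ACTION_SCALE

    # -- learning ----------------------------------------------------------

    def observe_transition(self, o, a_deg, r, o2, done) -> None:
        self.buffer.add(o, np.asarray(a_deg) / ACTION_SCALE,
                        r * self.config.reward_scale, o2, float(done))

    def update(self) -> Optional[tuple[float, float]]:
        cfg = self.config
        if self.buffer.size < max(cfg.batch_size, cfg.warmup_steps):
            return None
        o, a, r, o2, d = self.buffer.sample(cfg.batch_size, self.rng)
        # critic target: r + gamma (1-d) Q'(s', pi'(s'))
        a2 = self.target_actor(o2)
        q2 = self.target_critic(np.concatenate([o2, a2], axis=1))[:, 0]
        target = r + cfg.gamma * (1.0 - d) * q2
        sa = np.concatenate([o, a], axis=1)
        q, cache = self.critic.forward_cache(sa)
        td = q[:, 0] - target
        critic_loss = float(np.mean(td**2))
        grad_q = (2.0 / len(td)) * td[:, None]
        gW, gb, _ = self.critic.backward(cache, grad_q)
        self.opt_critic.step(self.critic.params(), gW + gb)

        # actor: ascend Q(s, pi(s))
        pi, a_cache = self.actor.forward_cache(o)
        sa_pi = np.concatenate([o, pi], axis=1)
        q_pi, c_cache = self.critic.forward_cache(sa_pi)
        actor_obj = float(np.mean(q_pi))
        ones = np.full((len(o), 1), -1.0 / len(o))  # minimize -Q
        _, _, grad_in = self.critic.backward(c_cache, ones)
        grad_a = grad_in[:, self.spec.obs_dim:]
        gW, gb, _ = self.actor.backward(a_cache, grad_a)
        self.opt_actor.step(self.actor.params(), gW + gb)

        # Polyak-average the targets
        for tgt, src in (
            (self.target_actor, self.actor),
            (self.target_critic, self.critic),
        ):
            for tp, sp in zip(tgt.params(), src.params()):
                tp += cfg.tau * (sp - tp)
        return critic_loss, actor_obj


def save_checkpoint(agent: DDPGAgent, path) -> None:
    """Checkpoint = npz of weights + sidecar JSON of the layout."""
    path = Path(path)
    arrays = {}
    for name, net in (("actor", agent.actor), ("critic", agent.critic),
                      ("target_actor", agent.target_actor),
                      ("target_critic", agent.target_critic)):
        for i, (w, b) in enumerate(zip(net.W, net.b)):
            arrays[f"{name}_W{i}"] = w
            arrays[f"{name}_b{i}"] = b
    np.savez(path, **arrays)
    meta = {
        "obs_dim": agent.spec.obs_dim,
        "action_dim": agent.spec.action_dim,
        "hidden": list(agent.config.hidden),
        "total_env_steps": agent.total_env_steps,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> DDPGAgent:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = AgentSpec(obs_dim=meta["obs_dim"], action_dim=meta["action_dim"],
                     hidden=tuple(meta["hidden"]))
    agent = DDPGAgent(spec, DDPGConfig(hidden=tuple(meta["hidden"])))
    data = np.load(path)
    for name, net in (("actor", agent.actor), ("critic", agent.critic),
                      ("target_actor", agent.target_actor),
                      ("target_critic", agent.target_critic)):
        for i in range(len(net.W)):
            net.W[i] = data[f"{name}_W{i}"]
            net.b[i] = data[f"{name}_b{i}"]
    agent.total_env_steps = int(meta.get("total_env_steps", 0))
    return agent


# ---------------------------------------------------------------------------
# Curriculum


@dataclass(frozen=True)
class CurriculumStage:
    u_min: float
    u_max: float
    budget_seconds: float


@dataclass(frozen=True)
class CurriculumSchedule:
    """Ordered wind stages with non-decreasing maximum wind."""

    stages: tuple[CurriculumStage, ...]

    def __post_init__(self) -> None:
        u = [s.u_max for s in self.stages]
        if any(b < a for a, b in zip(u, u[1:])):
            raise ValueError("stage u_max must be non-decreasing")

    @classmethod
    def from_stages(cls, raw) -> "CurriculumSchedule":
        return cls(tuple(
            CurriculumStage(float(s["u_min"]), float(s["u_max"]),
                            float(s["budget_seconds"]))
            for s in raw
        ))

    @classmethod
    def nominal(cls, budget: float = 4e6) -> "CurriculumSchedule":
        """Full-scale protocol: 0-2, 0-4, 0-6 m/s, several 1e6 s each."""
        return cls(tuple(
            CurriculumStage(0.0, u, budget) for u in (2.0, 4.0, 6.0)
        ))

    @classmethod
    def nominal_scaled(cls, budget: float = 2e5) -> "CurriculumSchedule":
        """Reduced-budget variant of the nominal wind stages."""
        return cls(tuple(
            CurriculumStage(0.0, u, budget) for u in (2.0, 4.0, 6.0)
        ))


@dataclass
class Checkpoint:
    simulated_seconds: float
    stage: int
    agent: DDPGAgent
    path: Optional[Path] = None


@dataclass
class TrainingResult:
    checkpoints: list[Checkpoint]
    log: pd.DataFrame
    simulated_seconds: float
    diverged: bool = False


def curriculum_train(
    schedule: CurriculumSchedule,
    config: Optional[DDPGConfig] = None,
    episode: Optional[EpisodeConfig] = None,
    seed: int = 0,
    glider: Optional[GliderParams] = None,
    thermal: Optional[ThermalParams] = None,
    checkpoint_dir: Optional[Path] = None,
    checkpoint_every: float = 50_000.0,
    reward_stability: bool = True,
    reward_center: bool = True,
    progress: bool = False,
) -> TrainingResult:
    """Train through the wind curriculum, carrying weights across stages.

    Returns the checkpoint series (always including the untrained initial
    state and the final state of every stage) and a per-episode training
    log with simulated time, return, stability and time-in-thermal
    fractions, and mean climb rate.  Divergence (non-finite weights or
    returns) aborts with ``diverged=True`` rather than failing silently.
    """
    config = config if config is not None else DDPGConfig()
    episode = episode if episode is not None else EpisodeConfig()
    glider = glider if glider is not None else vulture_params()
    thermal = thermal if thermal is not None else ThermalParams()
    spec = AgentSpec(obs_dim=6 * (episode.memory_size + 1),
                     hidden=tuple(config.hidden))
    agent = DDPGAgent(spec, config, seed=seed)
    rows = []
    checkpoints: list[Checkpoint] = []
    sim_time = 0.0
    next_ckpt = checkpoint_every
    diverged = False

    def snapshot(stage_idx: int) -> None:
        frozen = DDPGAgent(spec, config, seed=seed)
        frozen.actor = agent.actor.copy()
        frozen.critic = agent.critic.copy()
        frozen.target_actor = agent.target_actor.copy()
        frozen.target_critic = agent.target_critic.copy()
        frozen.total_env_steps = agent.total_env_steps
        ck = Checkpoint(simulated_seconds=sim_time, stage=stage_idx,
                        agent=frozen)
        if checkpoint_dir is not None:
            p = Path(checkpoint_dir) / f"ckpt_{int(sim_time):09d}.npz"
            save_checkpoint(frozen, p)
            ck.path = p
        checkpoints.append(ck)

    snapshot(stage_idx=-1)  # untrained initial policy
    ep_seed = seed
    for si, stage in enumerate(schedule.stages):
        stage_cfg = replace(episode, u_min=stage.u_min, u_max=stage.u_max)
        env = ThermalSoaringEnv(stage_cfg, glider, thermal,
                                reward_stability=reward_stability,
                                reward_center=reward_center)
        stage_time = 0.0
        while stage_time < stage.budget_seconds:
            ep_seed += 1
            obs = env.reset(seed=ep_seed)
            agent.reset_noise()
            done = False
            ep_ret = 0.0
            while not done:
                if agent.buffer.size < config.warmup_steps:
                    a = agent.random_action()
                else:
                    a = agent.act(obs, explore=True)
                obs2, r, done, info = env.step(a)
                agent.observe_transition(obs, a, r.total, obs2, done)
                for _ in range(config.update_every):
                    agent.update()
                obs = obs2
                ep_ret += r.total
                agent.total_env_steps += 1
            traj = env.trajectory()
            t_end = float(traj["t"].iloc[-1])
            stage_time += t_end
            sim_time += t_end
            rows.append({
                "simulated_seconds": sim_time,
                "stage": si,
                "u": info["u"],
                "episode_return": ep_ret,
                "stable_fraction": t_end / stage_cfg.duration,
                "fraction_in_thermal": fraction_in_thermal(traj),
                "mean_vz": float(traj["vz"].mean()),
                "crashed": bool(info["crashed"]),
                "unstable": bool(info["unstable"]),
            })
            if progress and len(rows) % 50 == 0:
                print(f"[train] t={sim_time:9.0f}s stage={si} "
                      f"ret={ep_ret:8.1f} stable={rows[-1]['stable_fraction']:.2f}")
            if not math.isfinite(ep_ret) or not all(
                np.isfinite(w).all() for w in agent.actor.W
            ):
                diverged = True
                break
            if sim_time >= next_ckpt:
                snapshot(si)
                next_ckpt += checkpoint_every
        snapshot(si)
        if diverged:
            break
    return TrainingResult(
        checkpoints=checkpoints,
        log=pd.DataFrame(rows),
        simulated_seconds=sim_time,
        diverged=diverged,
    )


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(
    agent: DDPGAgent,
    u: float,
    n_runs: int,
    seed: int = 0,
    episode: Optional[EpisodeConfig] = None,
    glider: Optional[GliderParams] = None,
    thermal: Optional[ThermalParams] = None,
    bounds: Optional[EfficiencyBounds] = None,
    keep_trajectories: bool = False,
):
    """Run seeded episodes at fixed wind with the deterministic policy.

    Returns a :class:`~thermosoar.metrics.PerformanceSummary`; with
    ``keep_trajectories`` also the list of trajectory tables.
    """
    episode = episode if episode is not None else EpisodeConfig()
    glider = glider if glider is not None else vulture_params()
    thermal = thermal if thermal is not None else ThermalParams()
    cfg = replace(episode, u_min=u, u_max=u)
    if bounds is None:
        opt, _ = optimal_climb_rate(glider, thermal, z=episode.z0)
        bounds = EfficiencyBounds(opt, baseline_climb_rate(glider))
    env = ThermalSoaringEnv(cfg, glider, thermal)
    vzs, fracs, rets, durs, trajs = [], [], [], [], []
    for i in range(n_runs):
        obs = env.reset(seed=seed * 1_000_003 + i)
        done = False
        ret = 0.0
        while not done:
            obs, r, done, info = env.step(agent.act(obs))
            ret += r.total
        traj = env.trajectory()
        vzs.append(float(traj["vz"].mean()))
        fracs.append(fraction_in_thermal(traj))
        rets.append(ret)
        durs.append(float(traj["t"].iloc[-1]))
        if keep_trajectories:
            trajs.append(traj)
    vzs_a = np.asarray(vzs)
    summary = PerformanceSummary(
        mean_vz=float(vzs_a.mean()) if n_runs else float("nan"),
        eta=(efficiency_eta(float(vzs_a.mean()), bounds)
             if n_runs else float("nan")),
        fraction_in_thermal=float(np.mean(fracs)) if n_runs else float("nan"),
        mean_distance_to_center=float("nan"),
        n_trajectories=n_runs,
        mean_duration=float(np.mean(durs)) if n_runs else float("nan"),
        per_run_vz=vzs_a,
        per_run_eta=np.array([efficiency_eta(v, bounds) for v in vzs]),
        per_run_fraction=np.asarray(fracs),
    )
    return (summary, trajs) if keep_trajectories else summary


def replay_observations(
    agent: DDPGAgent, trajs: Sequence[pd.DataFrame]
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the normalized observation sequence of logged trajectories.

    Uses the logged raw state columns (V, vz, sigma, alpha, theta, u) and
    the agent's memory length; returns (observations, theta series)
    concatenated over trajectories, for activation extraction.
    """
    from .environment import OBS_VARIABLES, observe

    memory = agent.spec.obs_dim // 6 - 1
    obs_rows, thetas = [], []
    for traj in trajs:
        history: list[dict] = []
        for _, row in traj.iterrows():
            history.append({v: float(row[v]) for v in OBS_VARIABLES})
            obs_rows.append(observe(history, memory))
            thetas.append(float(row["theta"]))
    return np.asarray(obs_rows), np.asarray(thetas)
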