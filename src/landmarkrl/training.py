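"""Deep Q-learning of the landmark-search policy.

Standard DQN machinery around the EsseNet approximator: a FIFO experience
replay sampled uniformly, an epsilon-greedy behavior policy with a linear
epsilon decay, a periodically synced frozen target network, and the squared
TD-error loss

    L(theta) = E[(r + gamma * max_a' Q(s', a'; theta-) - Q(s, a; theta))^2]

with bootstrapping masked on terminal transitions.  Optimization is Adam
with global gradient-norm clipping.  One episode = one volume (drawn
uniformly per episode), a uniformly random start in the central 80% of each
dimension, and steps of size ``rho_train`` until the target is reached, the
agent leaves the grid, or the step cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .essenet import (
    ArchitectureSpec,
    NetworkParams,
    backward_batch,
    forward_batch,
    init_params,
)
from .volume_env import (
    ActionCode,
    Landmark,
    ObservationSpec,
    Volume,
    observe,
    reset,
    step,
)

__all__ = [
    "Transition",
    "ReplayBuffer",
    "TrainConfig",
    "EpisodeLog",
    "AdamState",
    "epsilon_at",
    "select_action",
    "td_targets",
    "dqn_loss",
    "dqn_loss_and_grads",
    "adam_step",
    "sync_target",
    "run_training",
    "moving_average",
]


@dataclass(frozen=True)
class Transition:
    """One replay record ``(s, a, r, s', terminal)``."""

    s: np.ndarray
    a: ActionCode
    r: float
    s_next: np.ndarray
    terminal: bool

    def __post_init__(self) -> None:
        if self.s.shape != self.s_next.shape:
            raise ValueError(f"s and s' shapes differ: {self.s.shape} vs {self.s_next.shape}")
        if not np.isfinite(self.r):
            raise ValueError(f"reward must be finite, got {self.r}")


class ReplayBuffer:
    """FIFO ring of transitions with uniform without-replacement sampling."""

    def __init__(self, capacity: int = 150_000):
        if capacity < 1:
            raise ValueError("replay capacity must be >= 1")
        self.capacity = int(capacity)
        self._storage: list[Transition] = []
        self._next = 0  # ring write pointer once full

    def __len__(self) -> int:
        return len(self._storage)

    def push(self, t: Transition) -> None:
        if len(self._storage) < self.capacity:
            self._storage.append(t)
        else:
            self._storage[self._next] = t
            self._next = (self._next + 1) % self.capacity

    def sample(self, k: int, rng: np.random.Generator) -> list[Transition]:
        if k > len(self._storage):
            raise ValueError(
                f"cannot sample {k} transitions from a buffer of size {len(self._storage)}"
            )
        idx = rng.choice(len(self._storage), size=k, replace=False)
        return [self._storage[i] for i in idx]

    def oldest_first(self) -> list[Transition]:
        """Storage in insertion order (test hook for FIFO eviction)."""
        return self._storage[self._next :] + self._storage[: self._next]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the DQN training loop.

    Defaults follow the full-scale protocol: discount 0.9, epsilon decaying
    linearly 0.9 -> 0.1, batch 48, replay capacity 1.5e5, 1500-step episodes,
    coarse training step size rho=3 voxels.  ``update_every`` sets how many
    environment steps elapse per gradient step (1 = one update per step).
    """

    gamma: float = 0.9
    eps_start: float = 0.9
    eps_end: float = 0.1
    eps_decay_steps: int = 50_000
    batch_size: int = 48
    learning_rate: float = 1e-4
    target_sync_every: int = 2_500
    max_episode_steps: int = 1_500
    rho_train: int = 3
    episodes: int = 600
    seed: int = 0
    head_mode: str = "dueling"
    replay_capacity: int = 150_000
    warmup: int | None = None  # default: max(batch_size, 1000)
    update_every: int = 1
    reach_tol: float = 3.0
    grad_clip: float = 10.0
    reward_metric: str = "squared"
    # fine-rehearsal episodes: a fraction of episodes rehearse the test-time
    # refinement regime (unit steps from a start near the target, tighter
    # reach tolerance, short cap) so the net also learns the near-target,
    # small-step state distribution the fine localization phase visits.
    # 0 disables rehearsal (the full-scale protocol).
    fine_fraction: float = 0.0
    fine_rho: int = 1
    fine_reach_tol: float = 1.0
    fine_max_steps: int = 60
    fine_start_radius: tuple[float, float] = (2.0, 9.0)
    # rehearsal only starts after this fraction of episodes, so the far-field
    # (coarse-phase) policy is learned first under full exploration
    fine_start_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.eps_end > self.eps_start:
            raise ValueError("eps_end must be <= eps_start")
        if self.batch_size > self.replay_capacity:
            raise ValueError("batch_size must be <= replay_capacity")

    @property
    def warmup_size(self) -> int:
        return max(self.batch_size, 1000) if self.warmup is None else self.warmup


@dataclass(frozen=True)
class EpisodeLog:
    episode: int
    total_reward: float
    steps: int
    terminal_cause: str
    volume_id: int
    final_dist_vox: float
    final_dist_mm: float
    epsilon: float


def epsilon_at(step_idx: int, cfg: TrainConfig) -> float:
    """Linear interpolation from eps_start to eps_end over eps_decay_steps."""
    if step_idx < 0:
        raise ValueError("step index must be >= 0")
    if cfg.eps_decay_steps <= 0 or step_idx >= cfg.eps_decay_steps:
        return cfg.eps_end
    frac = step_idx / cfg.eps_decay_steps
    return cfg.eps_start + (cfg.eps_end - cfg.eps_start) * frac


def select_action(q: np.ndarray, eps: float, rng: np.random.Generator) -> ActionCode:
    """Epsilon-greedy over the 7 actions; greedy ties break to the lowest index."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {eps}")
    if eps > 0.0 and rng.random() < eps:
        return ActionCode(int(rng.integers(len(ActionCode))))
    return ActionCode(int(np.argmax(q)))


def _batch_arrays(batch: Sequence[Transition]):
    s = np.stack([t.s for t in batch])
    a = np.array([int(t.a) for t in batch])
    r = np.array([t.r for t in batch], dtype=np.float64)
    s_next = np.stack([t.s_next for t in batch])
    term = np.array([t.terminal for t in batch], dtype=bool)
    return s, a, r, s_next, term


def td_targets(
    batch: Sequence[Transition], target_params: NetworkParams, gamma: float
) -> np.ndarray:
    """``y = r + gamma * max_a' Q(s', a'; theta-)``; terminal items use ``y = r``."""
    _, _, r, s_next, term = _batch_arrays(batch)
    y = r.copy()
    boot = ~term
    if gamma > 0.0 and np.any(boot):
        q_next, _ = forward_batch(target_params, s_next[boot])
        y[boot] += gamma * q_next.max(axis=1)
    return y


def dqn_loss(
    batch: Sequence[Transition],
    params: NetworkParams,
    target_params: NetworkParams,
    gamma: float,
) -> float:
    """Mean squared TD error of the taken actions (targets are constants)."""
    loss, _ = dqn_loss_and_grads(batch, params, target_params, gamma, want_grads=False)
    return loss


def dqn_loss_and_grads(
    batch: Sequence[Transition],
    params: NetworkParams,
    target_params: NetworkParams,
    gamma: float,
    want_grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    s, a, _, _, _ = _batch_arrays(batch)
    y = td_targets(batch, target_params, gamma)
    q, cache = forward_batch(params, s)
    q_sa = q[np.arange(len(batch)), a]
    err = q_sa.astype(np.float64) - y
    loss = float(np.mean(err**2))
    if not want_grads:
        return loss, None
    dQ = np.zeros_like(q)
    dQ[np.arange(len(batch)), a] = (2.0 / len(batch)) * err
    grads = backward_batch(params, cache, dQ)
    return loss, grads


@dataclass
class AdamState:
    """First/second-moment accumulators for Adam."""

    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0

    @classmethod
    def for_params(cls, params: NetworkParams) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in params.items()},
            v={k: np.zeros_like(p) for k, p in params.items()},
        )


def adam_step(
    params: NetworkParams,
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    grad_clip: float = 10.0,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """In-place Adam update with global gradient-norm clipping."""
    if grad_clip > 0:
        norm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
        if norm > grad_clip:
            scale = grad_clip / norm
            grads = {k: g * scale for k, g in grads.items()}
    state.t += 1
    bc1 = 1.0 - beta1**state.t
    bc2 = 1.0 - beta2**state.t
    for k, g in grads.items():
        m, v = state.m[k], state.v[k]
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * np.square(g)
        denom = np.sqrt(v / bc2)
        denom += eps
        params.arrays[k] -= ((lr / bc1) * m / denom).astype(params.arrays[k].dtype)


def sync_target(params: NetworkParams) -> NetworkParams:
    """Deep copy; later updates to ``params`` leave the target untouched."""
    return params.copy()


def _near_target_start(
    landmark: Landmark,
    shape: Sequence[int],
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Random voxel at distance U(lo, hi) from the target, clamped to the grid."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    r = rng.uniform(*radius_range)
    p = np.rint(np.asarray(landmark.voxel) + r * u).astype(np.int64)
    return tuple(int(v) for v in np.clip(p, 0, np.asarray(shape) - 1))


def _central_start(shape: Sequence[int], rng: np.random.Generator) -> tuple[int, int, int]:
    """Uniform voxel within the central 80% of each dimension."""
    start = []
    for d in shape:
        lo = int(np.ceil(0.1 * (d - 1)))
        hi = int(np.floor(0.9 * (d - 1)))
        start.append(int(rng.integers(lo, hi + 1)))
    return tuple(start)


def run_training(
    dataset: Sequence[tuple[Volume, Landmark]],
    cfg: TrainConfig,
    spec: ObservationSpec,
    arch: ArchitectureSpec | None = None,
    on_episode: Callable[[EpisodeLog, NetworkParams], None] | None = None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Train an EsseNet agent on ``dataset`` and return (params, episode log).

    Fully reproducible given ``cfg.seed``: the seed is split into named
    substreams for network init, environment randomness (volume choice,
    start points, epsilon draws) and replay sampling.
    """
    if len(dataset) == 0:
        raise ValueError("run_training requires at least one (volume, landmark) pair")
    for i, (vol, lm) in enumerate(dataset):
        if lm is None:
            raise ValueError(f"volume {i} has no landmark")
        lm.validate_against(vol)

    if arch is None:
        arch = ArchitectureSpec(n=spec.n, frames=spec.frames, head_mode=cfg.head_mode)
    elif arch.n != spec.n or arch.frames != spec.frames:
        raise ValueError(
            f"architecture input ({arch.n}, {arch.frames}) does not match "
            f"observation spec ({spec.n}, {spec.frames})"
        )

    ss = np.random.SeedSequence(cfg.seed)
    init_ss, env_ss, replay_ss = ss.spawn(3)
    init_rng = np.random.default_rng(init_ss)
    env_rng = np.random.default_rng(env_ss)
    replay_rng = np.random.default_rng(replay_ss)

    params = init_params(arch, init_rng)
    target = sync_target(params)
    adam = AdamState.for_params(params)
    buffer = ReplayBuffer(cfg.replay_capacity)

    logs: list[EpisodeLog] = []
    global_step = 0
    for episode in range(cfg.episodes):
        vol_id = int(env_rng.integers(len(dataset)))
        volume, landmark = dataset[vol_id]
        fine = (
            episode >= cfg.fine_start_fraction * cfg.episodes
            and env_rng.random() < cfg.fine_fraction
        )
        if fine:
            start = _near_target_start(
                landmark, volume.shape, cfg.fine_start_radius, env_rng
            )
            rho, reach_tol = cfg.fine_rho, cfg.fine_reach_tol
            max_steps = min(cfg.fine_max_steps, cfg.max_episode_steps)
        else:
            start = _central_start(volume.shape, env_rng)
            rho, reach_tol = cfg.rho_train, cfg.reach_tol
            max_steps = cfg.max_episode_steps
        env = reset(volume, start, spec)
        stack = observe(volume, env, spec)
        total_reward = 0.0
        eps = epsilon_at(global_step, cfg)
        while not env.terminal:
            eps = epsilon_at(global_step, cfg)
            if env_rng.random() < eps:
                action = ActionCode(int(env_rng.integers(len(ActionCode))))
            else:
                q, _ = forward_batch(params, stack[None])
                action = ActionCode(int(np.argmax(q[0])))
            next_stack, reward, env = step(
                volume,
                env,
                action,
                rho,
                landmark,
                spec,
                max_steps=max_steps,
                reach_tol=reach_tol,
                reward_metric=cfg.reward_metric,
            )
            buffer.push(Transition(stack, action, reward, next_stack, env.terminal))
            total_reward += reward
            stack = next_stack
            global_step += 1
            if len(buffer) >= cfg.warmup_size and global_step % cfg.update_every == 0:
                batch = buffer.sample(cfg.batch_size, replay_rng)
                _, grads = dqn_loss_and_grads(batch, params, target, cfg.gamma)
                adam_step(params, grads, adam, cfg.learning_rate, cfg.grad_clip)
            if global_step % cfg.target_sync_every == 0:
                target = sync_target(params)

        final = np.asarray(env.position) - np.asarray(landmark.voxel)
        log = EpisodeLog(
            episode=episode,
            total_reward=total_reward,
            steps=env.step_count,
            terminal_cause=env.terminal_cause,
            volume_id=vol_id,
            final_dist_vox=float(np.linalg.norm(final)),
            final_dist_mm=float(np.linalg.norm(final * np.asarray(volume.spacing))),
            epsilon=eps,
        )
        logs.append(log)
        if on_episode is not None:
            on_episode(log, params)

    return params, pd.DataFrame([log.__dict__ for log in logs])


def moving_average(series: Sequence[float], window: int = 30) -> np.ndarray:
    """Trailing mean over the last ``min(window, t+1)`` points at each index."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=np.float64)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(len(x))
    lo = np.maximum(0, t + 1 - window)
    return (csum[t + 1] - csum[lo]) / (t + 1 - lo)
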