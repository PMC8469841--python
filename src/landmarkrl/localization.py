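"""Coarse-to-fine multi-agent localization at test time.

A trained agent first rolls out greedily from a start point (default: the
volume center) with a coarse step size for a fixed number of steps.  Five
fresh agents are then spawned at random displacements around the coarse
endpoint and refined with unit steps for a fixed number of steps; the final
prediction is a weighted average of the fine endpoints.  Rollouts never
terminate early: out-of-grid moves are clamped to the boundary so every
phase runs its full fixed iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .essenet import NetworkParams, forward
from .volume_env import (
    ACTION_VECTORS,
    ActionCode,
    EnvState,
    Landmark,
    ObservationSpec,
    Volume,
    observe,
)

__all__ = [
    "LocalizationConfig",
    "LocalizationResult",
    "QFunction",
    "greedy_rollout",
    "spawn_agents",
    "weighted_average",
    "localize",
    "evaluate",
]

# A policy is anything that maps (observation stack, position) to 7 Q-values.
QFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class LocalizationConfig:
    """Coarse-to-fine search protocol: step sizes, step counts, agent count.

    Defaults follow the two-phase schedule: ~100 coarse steps at rho=3, then
    5 agents spawned within ``spawn_radius`` voxels refined for ~50 steps at
    rho=1, combined by a weighted average (uniform by default;
    ``value_softmax`` weights agents by the softmax of their final state
    value and requires a dueling head).
    """

    rho_coarse: int = 3
    n_coarse_steps: int = 100
    n_agents: int = 5
    spawn_radius: float = 6.0
    rho_fine: int = 1
    n_fine_steps: int = 50
    weighting: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rho_coarse, self.rho_fine, self.n_agents) < 1:
            raise ValueError("step sizes and agent count must be >= 1")
        if min(self.n_coarse_steps, self.n_fine_steps) < 0:
            raise ValueError("step counts must be >= 0")
        if self.rho_fine > self.rho_coarse:
            raise ValueError("rho_fine must be <= rho_coarse")
        if self.weighting not in ("uniform", "value_softmax"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class LocalizationResult:
    start: tuple[int, int, int]
    coarse_endpoint: tuple[int, int, int]
    fine_endpoints: tuple[tuple[int, int, int], ...]
    weights: tuple[float, ...]
    predicted_voxel: tuple[int, int, int]
    predicted_world_mm: tuple[float, float, float]
    error_mm: float | None = None

    def to_dict(self) -> dict:
        d = {
            "start": list(self.start),
            "coarse_endpoint": list(self.coarse_endpoint),
            "fine_endpoints": [list(p) for p in self.fine_endpoints],
            "weights": list(self.weights),
            "predicted_voxel": list(self.predicted_voxel),
            "predicted_world_mm": list(self.predicted_world_mm),
        }
        if self.error_mm is not None:
            d["error_mm"] = self.error_mm
        return d


def _as_qfn(policy: NetworkParams | QFunction) -> QFunction:
    if isinstance(policy, NetworkParams):
        from .essenet import forward_batch

        def qfn(stack: np.ndarray, position: np.ndarray) -> np.ndarray:
            q, _ = forward_batch(policy, stack[None])
            return q[0]

        return qfn
    return policy


def greedy_rollout(
    volume: Volume,
    policy: NetworkParams | QFunction,
    start: Sequence[int],
    rho: int,
    n_steps: int,
    spec: ObservationSpec,
) -> list[tuple[int, int, int]]:
    """Pure-greedy rollout of exactly ``n_steps`` moves; returns all positions.

    ``policy`` is trained network parameters or any callable
    ``(stack, position) -> Q`` (useful for stub policies in tests).  Moves
    that would exit the grid are clamped per-axis to the boundary.
    """
    qfn = _as_qfn(policy)
    hi = np.asarray(volume.shape) - 1
    pos = np.asarray(start, dtype=np.int64)
    env = EnvState(position=tuple(int(v) for v in pos))
    trajectory = [tuple(int(v) for v in pos)]
    for _ in range(n_steps):
        stack = observe(volume, env, spec)
        q = qfn(stack, pos.copy())
        action = ActionCode(int(np.argmax(q)))
        new_pos = np.clip(pos + rho * ACTION_VECTORS[int(action)], 0, hi)
        history = (env.position, *env.history)[: spec.history]
        env = EnvState(position=tuple(int(v) for v in new_pos), history=history)
        pos = new_pos
        trajectory.append(tuple(int(v) for v in pos))
    return trajectory


def spawn_agents(
    center: Sequence[int],
    n: int,
    radius: float,
    rng: np.random.Generator,
    grid_shape: Sequence[int] | None = None,
) -> list[tuple[int, int, int]]:
    """``n`` points uniform in the L2 ball of ``radius`` around ``center``,
    rounded to voxels and clamped into the grid when a shape is given."""
    center = np.asarray(center, dtype=np.float64)
    points = []
    for _ in range(n):
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm == 0.0:
            direction = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        r = radius * rng.random() ** (1.0 / 3.0)
        p = center + (r / norm) * direction
        p = _round_half_away(p)
        if grid_shape is not None:
            p = np.clip(p, 0, np.asarray(grid_shape) - 1)
        points.append(tuple(int(v) for v in p))
    return points


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero, component-wise."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def weighted_average(points: Sequence[Sequence[int]], weights: Sequence[float]) -> tuple[int, int, int]:
    """Component-wise weighted mean rounded half away from zero."""
    w = np.asarray(weights, dtype=np.float64)
    if w.min() < 0 or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    mean = np.einsum("i,ij->j", w, np.asarray(points, dtype=np.float64))
    return tuple(int(v) for v in _round_half_away(mean))


def localize(
    volume: Volume,
    policy: NetworkParams | QFunction,
    cfg: LocalizationConfig,
    spec: ObservationSpec,
    start: Sequence[int] | None = None,
    gt: Landmark | None = None,
) -> LocalizationResult:
    """Run the full coarse-to-fine procedure; deterministic given ``cfg.seed``.

    Untrained parameters are accepted without complaint -- prediction quality
    is the caller's concern.  If ``gt`` is given the Euclidean mm error of
    the prediction is included in the result.
    """
    if start is None:
        start = tuple(int(d // 2) for d in volume.shape)
    rng = np.random.default_rng(cfg.seed)

    coarse = greedy_rollout(volume, policy, start, cfg.rho_coarse, cfg.n_coarse_steps, spec)
    coarse_end = coarse[-1]

    seeds = spawn_agents(coarse_end, cfg.n_agents, cfg.spawn_radius, rng, volume.shape)
    fine_ends = []
    for seed_pos in seeds:
        traj = greedy_rollout(volume, policy, seed_pos, cfg.rho_fine, cfg.n_fine_steps, spec)
        fine_ends.append(traj[-1])

    if cfg.weighting == "uniform":
        weights = np.full(cfg.n_agents, 1.0 / cfg.n_agents)
    else:  # value_softmax
        if not isinstance(policy, NetworkParams) or policy.arch.head_mode != "dueling":
            raise ValueError("value_softmax weighting requires dueling-head network parameters")
        values = []
        for p in fine_ends:
            trace = forward(observe(volume, EnvState(position=p), spec), policy)
            values.append(trace.V)
        v = np.asarray(values, dtype=np.float64)
        v -= v.max()
        weights = np.exp(v) / np.exp(v).sum()

    predicted = weighted_average(fine_ends, weights)
    world = tuple(float(x) for x in volume.world_from_voxel(predicted))
    error = None if gt is None else evaluate(predicted, gt, volume.spacing)
    return LocalizationResult(
        start=tuple(int(v) for v in start),
        coarse_endpoint=coarse_end,
        fine_endpoints=tuple(fine_ends),
        weights=tuple(float(w) for w in weights),
        predicted_voxel=predicted,
        predicted_world_mm=world,
        error_mm=error,
    )


def evaluate(
    predicted: Sequence[int], gt: Landmark, spacing: Sequence[float]
) -> float:
    """Euclidean distance between prediction and ground truth, in mm."""
    delta = (np.asarray(predicted) - np.asarray(gt.voxel)) * np.asarray(spacing)
    return float(np.linalg.norm(delta))
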