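"""Volumes, landmarks, 2.5D historical observations, and the search MDP.

A 3D scan is the agent's environment: the agent occupies a voxel, observes a
stack of 2.5D patches (three orthogonal slices through its position, for the
current and the last ``H`` positions), and moves in unit steps of size ``rho``
along the grid axes until it reaches the target landmark, leaves the grid, or
exhausts its step budget.  Rewards are the decrease in (squared) Euclidean
distance to the target, so the return over a trajectory telescopes to
``d(p_0, gt)^2 - d(p_T, gt)^2``.

Conventions
-----------
* Voxel indices are 0-based with axis order ``(x, y, z)``;
  ``world = origin + index * spacing`` (mm).
* Patches normal to axis ``x`` are indexed ``(y, z)``, normal to ``y`` are
  ``(x, z)``, normal to ``z`` are ``(x, y)``.
* A patch of side ``N`` centered at ``c`` covers in-plane indices
  ``c - N//2 .. c - N//2 + N - 1`` (even ``N`` is left-biased by one voxel).
* Intensities are windowed linearly from ``[lo, hi]`` to ``[0, 1]`` with
  clipping; samples outside the grid take ``pad_value`` (default: the window
  minimum, i.e. 0 after normalization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Volume",
    "Landmark",
    "ObservationSpec",
    "ActionCode",
    "ACTION_VECTORS",
    "EnvState",
    "TerminalCause",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "extract_plane_patch",
    "observe",
    "apply_action",
    "compute_reward",
    "reset",
    "step",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and world origin in mm.

    ``data`` is indexed ``(x, y, z)``.  ``world_from_voxel`` maps voxel
    indices to mm assuming an axis-aligned scan.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # cache of windowed+padded arrays keyed by (n, window, pad); see observe()
    _obs_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be a non-empty 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def contains(self, voxel: Sequence[int]) -> bool:
        v = np.asarray(voxel)
        return bool(np.all(v >= 0) and np.all(v < np.array(self.shape)))

    def world_from_voxel(self, voxel: Sequence[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(voxel) * np.asarray(self.spacing)

    def voxel_from_world(self, world_mm: Sequence[float]) -> np.ndarray:
        return (np.asarray(world_mm) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class Landmark:
    """A named target point, stored both as a voxel index and in mm."""

    name: str
    voxel: tuple[int, int, int]
    world_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxel", tuple(int(v) for v in self.voxel))
        object.__setattr__(self, "world_mm", tuple(float(w) for w in self.world_mm))

    @classmethod
    def from_voxel(cls, name: str, voxel: Sequence[int], volume: Volume) -> "Landmark":
        world = volume.world_from_voxel(voxel)
        return cls(name, tuple(int(v) for v in voxel), tuple(float(w) for w in world))

    def validate_against(self, volume: Volume, atol_vox: float = 0.5) -> None:
        """Check bounds and voxel/world consistency within ``atol_vox`` voxels."""
        if not volume.contains(self.voxel):
            raise ValueError(
                f"landmark {self.name!r} voxel {self.voxel} outside volume of shape {volume.shape}"
            )
        back = volume.voxel_from_world(self.world_mm)
        if np.max(np.abs(back - np.asarray(self.voxel))) > atol_vox:
            raise ValueError(
                f"landmark {self.name!r}: world_mm {self.world_mm} maps to voxel {back}, "
                f"inconsistent with stored voxel {self.voxel}"
            )


@dataclass(frozen=True)
class ObservationSpec:
    """Geometry and normalization of the 2.5D observation stack.

    ``n``        patch side length in voxels.
    ``history``  number of PAST frames kept (``H``); the stack holds ``H+1``.
    ``window``   intensity window ``(lo, hi)`` mapped linearly to ``[0, 1]``.
    ``pad_value`` raw intensity used outside the grid (default: window lo).
    """

    n: int = 32
    history: int = 3
    window: tuple[float, float] = (0.0, 1.0)
    pad_value: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"patch side n must be >= 3, got {self.n}")
        if self.history < 0:
            raise ValueError(f"history must be >= 0, got {self.history}")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window must satisfy lo < hi, got {self.window}")

    @property
    def frames(self) -> int:
        return self.history + 1

    @property
    def pad(self) -> float:
        return self.window[0] if self.pad_value is None else self.pad_value

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        lo, hi = self.window
        return (np.clip(raw, lo, hi) - lo) / (hi - lo)


class ActionCode(IntEnum):
    """The seven moves: six unit axis displacements plus a stationary action.

    Order is fixed (argmax ties break toward the lowest index).
    """

    POS_X = 0
    NEG_X = 1
    POS_Y = 2
    NEG_Y = 3
    POS_Z = 4
    NEG_Z = 5
    STAY = 6

    @property
    def vector(self) -> np.ndarray:
        return ACTION_VECTORS[self.value]


ACTION_VECTORS = np.array(
    [
        [1, 0, 0],
        [-1, 0, 0],
        [0, 1, 0],
        [0, -1, 0],
        [0, 0, 1],
        [0, 0, -1],
        [0, 0, 0],
    ],
    dtype=np.int64,
)


class TerminalCause:
    NONE = "none"
    REACHED_TARGET = "reached_target"
    OUT_OF_BOUNDS = "out_of_bounds"
    MAX_STEPS = "max_steps"


@dataclass(frozen=True)
class EnvState:
    """Immutable snapshot of the agent: position, recent history, termination."""

    position: tuple[int, int, int]
    history: tuple[tuple[int, int, int], ...] = ()  # most recent first, length <= H
    step_count: int = 0
    terminal_cause: str = TerminalCause.NONE

    @property
    def terminal(self) -> bool:
        return self.terminal_cause != TerminalCause.NONE


# ---------------------------------------------------------------------------
# Volume and landmark I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mhd``/``.mha``) volume.

    The array is returned in ``(x, y, z)`` index order with spacing (mm) and
    origin taken from the file header.  Non-positive spacing is rejected
    rather than silently replaced.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith((".mhd", ".mha")):
        return _read_metaimage(path)
    raise IOError(f"unsupported volume format: {path} (expected .nii/.nii.gz/.mhd/.mha)")


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - normalize to IOError
        raise IOError(f"failed to read NIfTI volume {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise IOError(f"NIfTI volume {path} has invalid voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _read_metaimage(path: Path) -> Volume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"failed to read MetaImage volume {path}: {exc}") from exc
    spacing = img.GetSpacing()  # already (x, y, z)
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise IOError(f"MetaImage volume {path} has invalid voxel spacing {spacing}")
    return Volume(
        data=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    elif name.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise IOError(f"unsupported volume format: {path}")


def write_landmarks(landmarks: Sequence[Landmark], path: str | Path) -> None:
    records = [
        {"name": lm.name, "voxel": list(lm.voxel), "world_mm": list(lm.world_mm)}
        for lm in landmarks
    ]
    Path(path).write_text(json.dumps(records, indent=2))


def read_landmarks(path: str | Path, volume: Volume | None = None) -> list[Landmark]:
    """Read landmark records; validate against ``volume`` bounds if supplied."""
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed landmark file {path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(records, list):
        raise ValueError(f"malformed landmark file {path}: expected a JSON list of records")
    landmarks = []
    for i, rec in enumerate(records):
        for key in ("name", "voxel", "world_mm"):
            if key not in rec:
                raise ValueError(f"landmark record {i} in {path} is missing key {key!r}")
        lm = Landmark(rec["name"], tuple(rec["voxel"]), tuple(rec["world_mm"]))
        if volume is not None:
            lm.validate_against(volume)
        landmarks.append(lm)
    return landmarks


# ---------------------------------------------------------------------------
# 2.5D observation extraction
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def extract_plane_patch(
    volume: Volume, center: Sequence[int], axis: str | int, spec: ObservationSpec
) -> np.ndarray:
    """Extract the normalized ``N x N`` slice through ``center`` normal to ``axis``.

    The center may lie anywhere (including outside the grid); out-of-grid
    samples take ``spec.pad``.  This is the reference implementation; the
    cached fast path used by :func:`observe` must agree with it exactly.
    """
    ax = _AXIS_INDEX[axis]
    in_plane = [a for a in range(3) if a != ax]
    n = spec.n
    half = n // 2
    raw = np.full((n, n), spec.pad, dtype=np.float64)
    c = np.asarray(center, dtype=np.int64)
    k = int(c[ax])
    if 0 <= k < volume.shape[ax]:
        starts = [int(c[a]) - half for a in in_plane]
        dims = [volume.shape[a] for a in in_plane]
        src_lo = [max(0, s) for s in starts]
        src_hi = [min(d, s + n) for s, d in zip(starts, dims)]
        if all(lo < hi for lo, hi in zip(src_lo, src_hi)):
            idx: list = [None, None, None]
            idx[ax] = k
            idx[in_plane[0]] = slice(src_lo[0], src_hi[0])
            idx[in_plane[1]] = slice(src_lo[1], src_hi[1])
            block = volume.data[tuple(idx)]
            dst0 = slice(src_lo[0] - starts[0], src_hi[0] - starts[0])
            dst1 = slice(src_lo[1] - starts[1], src_hi[1] - starts[1])
            raw[dst0, dst1] = block
    return spec.normalize(raw)


def _padded_normalized(volume: Volume, spec: ObservationSpec) -> tuple[np.ndarray, int]:
    """Windowed copy of the volume padded by ``n`` voxels per side (cached)."""
    key = (spec.n, spec.window, spec.pad)
    cached = volume._obs_cache.get(key)
    if cached is None:
        pad = spec.n
        norm = spec.normalize(np.asarray(volume.data, dtype=np.float32))
        padded = np.full(
            tuple(s + 2 * pad for s in volume.shape),
            spec.normalize(np.array(spec.pad)),
            dtype=np.float32,
        )
        padded[pad:-pad, pad:-pad, pad:-pad] = norm
        cached = (padded, pad)
        volume._obs_cache[key] = cached
    return cached


def _three_planes(volume: Volume, center: Sequence[int], spec: ObservationSpec) -> np.ndarray:
    """Fast (3, n, n) patch extraction via the padded cache."""
    padded, pad = _padded_normalized(volume, spec)
    n, half = spec.n, spec.n // 2
    c = np.asarray(center, dtype=np.int64) + pad
    # positions farther than n outside the grid clamp onto pure padding;
    # the clamp range keeps every slice below in-bounds
    c = np.clip(c, half, np.array(padded.shape) - (n - half))
    out = np.empty((3, n, n), dtype=np.float32)
    x, y, z = (int(v) for v in c)
    out[0] = padded[x, y - half : y - half + n, z - half : z - half + n]
    out[1] = padded[x - half : x - half + n, y, z - half : z - half + n]
    out[2] = padded[x - half : x - half + n, y - half : y - half + n, z]
    return out


def _positions_for_frames(env: EnvState, spec: ObservationSpec) -> list[tuple[int, int, int]]:
    """Position at time t-h for h = 0..H, replicating the oldest when short."""
    avail = [env.position, *env.history]
    return [avail[min(h, len(avail) - 1)] for h in range(spec.frames)]


def observe(volume: Volume, env: EnvState, spec: ObservationSpec) -> np.ndarray:
    """Build the ``(H+1, 3, N, N)`` observation stack for the current state.

    Frame ``h`` holds the three orthogonal patches at the position ``h`` steps
    in the past; at episode start all frames replicate the current position.
    The returned array is freshly allocated (by-value contract).
    """
    positions = _positions_for_frames(env, spec)
    stack = np.empty((spec.frames, 3, spec.n, spec.n), dtype=np.float32)
    seen: dict[tuple[int, int, int], int] = {}
    for h, pos in enumerate(positions):
        key = tuple(int(v) for v in pos)
        if key in seen:
            stack[h] = stack[seen[key]]
        else:
            stack[h] = _three_planes(volume, pos, spec)
            seen[key] = h
    return stack


# ---------------------------------------------------------------------------
# MDP dynamics
# ---------------------------------------------------------------------------

def apply_action(p: Sequence[int], action: ActionCode, rho: int) -> np.ndarray:
    """``p_{i+1} = p_i + rho * a`` with unit displacement ``a`` (no clamping)."""
    if rho < 1:
        raise ValueError(f"step size rho must be a positive integer, got {rho}")
    return np.asarray(p, dtype=np.int64) + int(rho) * ACTION_VECTORS[int(action)]


def compute_reward(
    p_i: Sequence[int],
    p_next: Sequence[int],
    p_gt: Sequence[int],
    metric: str = "squared",
) -> float:
    """Distance-based reward: positive when the move brings the agent closer.

    ``squared`` (default): ``||p_i - gt||^2 - ||p_next - gt||^2`` in voxel
    units (integer-exact, telescopes over a trajectory).  ``plain`` uses the
    unsquared Euclidean distances.
    """
    p_i = np.asarray(p_i, dtype=np.int64)
    p_next = np.asarray(p_next, dtype=np.int64)
    p_gt = np.asarray(p_gt, dtype=np.int64)
    d2_i = int(np.sum((p_i - p_gt) ** 2))
    d2_next = int(np.sum((p_next - p_gt) ** 2))
    if metric == "squared":
        return float(d2_i - d2_next)
    if metric == "plain":
        return float(np.sqrt(d2_i) - np.sqrt(d2_next))
    raise ValueError(f"unknown reward metric {metric!r} (expected 'squared' or 'plain')")


def reset(volume: Volume, start: Sequence[int], spec: ObservationSpec) -> EnvState:
    """Start an episode at ``start`` with an empty history."""
    del volume, spec  # signature kept uniform; start need not be validated
    return EnvState(position=tuple(int(v) for v in start))


def step(
    volume: Volume,
    env: EnvState,
    action: ActionCode,
    rho: int,
    gt: Landmark,
    spec: ObservationSpec,
    max_steps: int = 1500,
    reach_tol: float = 3.0,
    reward_metric: str = "squared",
) -> tuple[np.ndarray, float, EnvState]:
    """Advance the MDP one transition and return ``(stack, reward, new_state)``.

    Termination causes, in precedence order: ``reached_target`` when the new
    position is within ``reach_tol`` voxels of the target, ``out_of_bounds``
    when it leaves the grid, ``max_steps`` when the step budget is exhausted.
    """
    if env.terminal:
        raise RuntimeError(f"cannot step a terminal environment (cause: {env.terminal_cause})")
    p_next = apply_action(env.position, action, rho)
    reward = compute_reward(env.position, p_next, gt.voxel, metric=reward_metric)
    step_count = env.step_count + 1

    dist = float(np.linalg.norm(p_next - np.asarray(gt.voxel)))
    if dist <= reach_tol:
        cause = TerminalCause.REACHED_TARGET
    elif not volume.contains(p_next):
        cause = TerminalCause.OUT_OF_BOUNDS
    elif step_count >= max_steps:
        cause = TerminalCause.MAX_STEPS
    else:
        cause = TerminalCause.NONE

    history = (env.position, *env.history)[: spec.history]
    new_env = EnvState(
        position=tuple(int(v) for v in p_next),
        history=history,
        step_count=step_count,
        terminal_cause=cause,
    )
    stack = observe(volume, new_env, spec)
    return stack, reward, new_env
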