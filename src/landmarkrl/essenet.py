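"""Explicit spatio-sequential encoding Q-network (EsseNet) in pure NumPy.

The network scores the seven moves from a ``(H+1, 3, N, N)`` stack of 2.5D
observations.  Its structure mirrors the factorization of the state:

* a convolutional encoder ``xi_j`` per image axis ``j`` (three encoders whose
  parameters are *shared across frames* but *not across axes*), producing a
  per-plane code ``t[h, j]``;
* a per-frame local-inference layer ``psi_h`` (one fully connected layer per
  frame ``h``, *not shared*) fusing the three plane codes into ``T_bar[h]``;
* a global fully connected layer over the concatenated frame codes ``s_bar``;
* either a dueling pair of heads -- state value ``V`` (parameters ``beta``)
  and action advantage ``A`` (parameters ``alpha``) aggregated as
  ``Q = V + (A - mean(A))`` -- or a single plain linear Q head.

Everything here is NumPy: forward, reverse-mode gradients (used by the
training module), He-uniform initialization, and a MAC-counting FLOPs
accountant.  Convolutions use im2col so the heavy lifting is BLAS matmuls.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "ArchitectureSpec",
    "NetworkParams",
    "ForwardTrace",
    "ConfigurationError",
    "init_params",
    "forward",
    "forward_batch",
    "backward_batch",
    "dueling_aggregate",
    "count_flops",
    "flops_breakdown",
    "save_params",
    "load_params",
]

AXES = ("x", "y", "z")
N_ACTIONS = 7


class ConfigurationError(ValueError):
    """Raised when inputs or checkpoints do not match the architecture."""


# ---------------------------------------------------------------------------
# Architecture description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Serializable description of an EsseNet; FLOPs are computable from it alone.

    The default widths are the reference configuration: three stride-2 3x3
    conv layers (1->8->16->32, 'same' padding) followed by a linear layer to
    ``encoder_fc`` features per plane; a per-frame local layer to
    ``local_width``; a global layer to ``global_width``; and the heads.
    """

    n: int = 32
    frames: int = 4
    encoder_channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    stride: int = 2
    encoder_fc: int = 64
    local_width: int = 64
    global_width: int = 128
    head_mode: str = "dueling"

    def __post_init__(self) -> None:
        if self.head_mode not in ("dueling", "plain"):
            raise ConfigurationError(f"head_mode must be 'dueling' or 'plain', got {self.head_mode!r}")
        if self.conv_sizes()[-1] < 1:
            raise ConfigurationError(f"patch side n={self.n} collapses below 1 px in the encoder")

    def conv_sizes(self) -> list[int]:
        """Spatial side after each conv layer ('same' padding, given stride)."""
        sizes, s = [], self.n
        pad = self.kernel // 2
        for _ in self.encoder_channels:
            s = (s + 2 * pad - self.kernel) // self.stride + 1
            sizes.append(s)
        return sizes

    @property
    def encoder_flat(self) -> int:
        return self.encoder_channels[-1] * self.conv_sizes()[-1] ** 2

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        shapes: dict[str, tuple[int, ...]] = {}
        for ax in AXES:
            in_c = 1
            for i, out_c in enumerate(self.encoder_channels):
                shapes[f"enc_{ax}_conv{i}_W"] = (out_c, in_c, self.kernel, self.kernel)
                shapes[f"enc_{ax}_conv{i}_b"] = (out_c,)
                in_c = out_c
            shapes[f"enc_{ax}_fc_W"] = (self.encoder_fc, self.encoder_flat)
            shapes[f"enc_{ax}_fc_b"] = (self.encoder_fc,)
        for h in range(self.frames):
            shapes[f"local_{h}_W"] = (self.local_width, 3 * self.encoder_fc)
            shapes[f"local_{h}_b"] = (self.local_width,)
        shapes["global_W"] = (self.global_width, self.frames * self.local_width)
        shapes["global_b"] = (self.global_width,)
        if self.head_mode == "dueling":
            shapes["value_W"] = (1, self.global_width)
            shapes["value_b"] = (1,)
            shapes["adv_W"] = (N_ACTIONS, self.global_width)
            shapes["adv_b"] = (N_ACTIONS,)
        else:
            shapes["q_W"] = (N_ACTIONS, self.global_width)
            shapes["q_b"] = (N_ACTIONS,)
        return shapes

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureSpec":
        d = json.loads(s)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        return cls(**d)


@dataclass
class NetworkParams:
    """All learnable parameters, partitioned as Theta / Omega / global / alpha / beta."""

    arch: ArchitectureSpec
    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.arrays.items())

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.arch, {k: v.copy() for k, v in self.arrays.items()})

    # --- the partition of Eq.-level symbols into named groups ---------------
    def theta(self, axis: str) -> dict[str, np.ndarray]:
        """Conv-encoder parameters for one image axis (shared across frames)."""
        return {k: v for k, v in self.arrays.items() if k.startswith(f"enc_{axis}_")}

    def omega(self, h: int) -> dict[str, np.ndarray]:
        """Per-frame local-inference parameters (not shared across frames)."""
        return {k: v for k, v in self.arrays.items() if k.startswith(f"local_{h}_")}

    def global_inference(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.arrays.items() if k.startswith("global_")}

    def beta(self) -> dict[str, np.ndarray]:
        """State-value head V."""
        return {k: v for k, v in self.arrays.items() if k.startswith("value_")}

    def alpha(self) -> dict[str, np.ndarray]:
        """Action-advantage head A."""
        return {k: v for k, v in self.arrays.items() if k.startswith("adv_")}


def init_params(
    arch: ArchitectureSpec, rng: np.random.Generator, dtype=np.float32
) -> NetworkParams:
    """He-uniform weights (limit sqrt(6/fan_in)), zero biases."""
    arrays: dict[str, np.ndarray] = {}
    for name, shape in arch.param_shapes().items():
        if name.endswith("_b"):
            arrays[name] = np.zeros(shape, dtype=dtype)
        else:
            fan_in = int(np.prod(shape[1:]))
            limit = np.sqrt(6.0 / fan_in)
            arrays[name] = rng.uniform(-limit, limit, size=shape).astype(dtype)
    return NetworkParams(arch, arrays)


# ---------------------------------------------------------------------------
# Layer primitives (im2col convolution, FC, ReLU) with reverse-mode gradients
# ---------------------------------------------------------------------------

def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the two trailing axes (cheaper than np.pad for this case)."""
    if pad == 0:
        return x
    B, C, H, W = x.shape
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=x.dtype)
    xp[:, :, pad : pad + H, pad : pad + W] = x
    return xp


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, oh, ow, C, k, k) patch tensor."""
    xp = _pad2d(x, pad)
    B, C, H, W = xp.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    sb, sc, sh, sw = xp.strides
    cols = as_strided(
        xp,
        shape=(B, C, oh, ow, k, k),
        strides=(sb, sc, sh * stride, sw * stride, sh, sw),
    )
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    out_c, in_c, k, _ = W.shape
    pad = k // 2
    cols = _im2col(x, k, stride, pad)  # (B, oh, ow, C, k, k)
    B, oh, ow = cols.shape[:3]
    flat = cols.reshape(B * oh * ow, in_c * k * k)
    y = flat @ W.reshape(out_c, -1).T + b
    y = y.reshape(B, oh, ow, out_c).transpose(0, 3, 1, 2)
    return y, (flat, x.shape, (oh, ow), stride)


def _conv_backward(
    dy: np.ndarray, W: np.ndarray, cache, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    flat, x_shape, (oh, ow), stride = cache
    out_c, in_c, k, _ = W.shape
    pad = k // 2
    B = x_shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(B * oh * ow, out_c)
    dW = (dyf.T @ flat).reshape(W.shape)
    db = dyf.sum(axis=0)
    if not need_dx:
        return None, dW, db
    dcols = (dyf @ W.reshape(out_c, -1)).reshape(B, oh, ow, in_c, k, k)
    H, Wd = x_shape[2], x_shape[3]
    dxp = np.zeros((B, in_c, H + 2 * pad, Wd + 2 * pad), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd]
    return dx, dW, db


def _fc_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W.T + b, x


def _fc_backward(dy: np.ndarray, W: np.ndarray, x: np.ndarray):
    return dy @ W, dy.T @ x, dy.sum(axis=0)


def _relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, y


def _relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------

@dataclass
class ForwardTrace:
    """Intermediate encodings of a single observation stack.

    ``t``      (frames, 3, encoder_fc)  per-plane codes t[h, j]
    ``T``      (frames, 3*encoder_fc)   concatenated plane codes per frame
    ``T_bar``  (frames, local_width)    local-inference outputs
    ``s_bar``  (frames*local_width,)    global-inference input
    ``V``      float | None             state value (dueling only)
    ``A``      (7,) | None              action advantages (dueling only)
    ``Q``      (7,)                     action values
    """

    t: np.ndarray
    T: np.ndarray
    T_bar: np.ndarray
    s_bar: np.ndarray
    V: float | None
    A: np.ndarray | None
    Q: np.ndarray


def _check_stack(stack: np.ndarray, arch: ArchitectureSpec, layer: str) -> None:
    expected = (arch.frames, 3, arch.n, arch.n)
    if stack.shape[-4:] != expected:
        raise ConfigurationError(
            f"{layer}: observation stack shape {stack.shape} does not match "
            f"architecture input {expected}"
        )


def forward_batch(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, dict]:
    """Batched forward pass: ``X`` is ``(B, frames, 3, n, n)``; returns (Q, cache)."""
    arch = params.arch
    _check_stack(X, arch, "encoder input")
    B, F = X.shape[0], arch.frames
    dtype = params["global_W"].dtype
    X = np.ascontiguousarray(X, dtype=dtype)
    cache: dict = {"X_shape": X.shape}
    t = np.empty((B, F, 3, arch.encoder_fc), dtype=dtype)
    for j, ax in enumerate(AXES):
        h = X[:, :, j].reshape(B * F, 1, arch.n, arch.n)
        layer_caches = []
        for i in range(len(arch.encoder_channels)):
            h, c_conv = _conv_forward(h, params[f"enc_{ax}_conv{i}_W"], params[f"enc_{ax}_conv{i}_b"], arch.stride)
            h, c_relu = _relu_forward(h)
            layer_caches.append((c_conv, c_relu))
        flat = h.reshape(B * F, -1)
        z, c_fc = _fc_forward(flat, params[f"enc_{ax}_fc_W"], params[f"enc_{ax}_fc_b"])
        z, c_r = _relu_forward(z)
        layer_caches.append((c_fc, c_r, h.shape))
        cache[f"enc_{ax}"] = layer_caches
        t[:, :, j] = z.reshape(B, F, arch.encoder_fc)
    T = t.reshape(B, F, 3 * arch.encoder_fc)
    T_bar = np.empty((B, F, arch.local_width), dtype=dtype)
    cache["local"] = []
    for h_idx in range(F):
        z, c_fc = _fc_forward(T[:, h_idx], params[f"local_{h_idx}_W"], params[f"local_{h_idx}_b"])
        z, c_r = _relu_forward(z)
        cache["local"].append((c_fc, c_r))
        T_bar[:, h_idx] = z
    s_bar = T_bar.reshape(B, F * arch.local_width)
    g, c_gfc = _fc_forward(s_bar, params["global_W"], params["global_b"])
    g, c_gr = _relu_forward(g)
    cache["global"] = (c_gfc, c_gr)
    cache["t"], cache["T"], cache["T_bar"], cache["s_bar"], cache["g"] = t, T, T_bar, s_bar, g
    if arch.head_mode == "dueling":
        V, c_v = _fc_forward(g, params["value_W"], params["value_b"])
        A, c_a = _fc_forward(g, params["adv_W"], params["adv_b"])
        Q = dueling_aggregate(V, A)
        cache["heads"] = (c_v, c_a)
        cache["V"], cache["A"] = V, A
    else:
        Q, c_q = _fc_forward(g, params["q_W"], params["q_b"])
        cache["heads"] = (c_q,)
        cache["V"] = cache["A"] = None
    return Q, cache


def backward_batch(params: NetworkParams, cache: dict, dQ: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter, given dLoss/dQ."""
    arch = params.arch
    B, F = cache["X_shape"][0], arch.frames
    grads: dict[str, np.ndarray] = {}
    if arch.head_mode == "dueling":
        c_v, c_a = cache["heads"]
        # Q = V + A - mean_a(A):  dV = sum_a dQ;  dA = dQ - mean_a(dQ)
        dV = dQ.sum(axis=1, keepdims=True)
        dA = dQ - dQ.mean(axis=1, keepdims=True)
        dg_v, grads["value_W"], grads["value_b"] = _fc_backward(dV, params["value_W"], c_v)
        dg_a, grads["adv_W"], grads["adv_b"] = _fc_backward(dA, params["adv_W"], c_a)
        dg = dg_v + dg_a
    else:
        (c_q,) = cache["heads"]
        dg, grads["q_W"], grads["q_b"] = _fc_backward(dQ, params["q_W"], c_q)
    c_gfc, c_gr = cache["global"]
    dg = _relu_backward(dg, c_gr)
    ds_bar, grads["global_W"], grads["global_b"] = _fc_backward(dg, params["global_W"], c_gfc)
    dT_bar = ds_bar.reshape(B, F, arch.local_width)
    dT = np.empty((B, F, 3 * arch.encoder_fc), dtype=ds_bar.dtype)
    for h_idx in range(F):
        c_fc, c_r = cache["local"][h_idx]
        dz = _relu_backward(dT_bar[:, h_idx], c_r)
        dT[:, h_idx], grads[f"local_{h_idx}_W"], grads[f"local_{h_idx}_b"] = _fc_backward(
            dz, params[f"local_{h_idx}_W"], c_fc
        )
    dt = dT.reshape(B, F, 3, arch.encoder_fc)
    for j, ax in enumerate(AXES):
        layer_caches = cache[f"enc_{ax}"]
        c_fc, c_r, conv_out_shape = layer_caches[-1]
        dz = _relu_backward(dt[:, :, j].reshape(B * F, arch.encoder_fc), c_r)
        dflat, grads[f"enc_{ax}_fc_W"], grads[f"enc_{ax}_fc_b"] = _fc_backward(
            dz, params[f"enc_{ax}_fc_W"], c_fc
        )
        dh = dflat.reshape(conv_out_shape)
        for i in range(len(arch.encoder_channels) - 1, -1, -1):
            c_conv, c_relu = layer_caches[i]
            dh = _relu_backward(dh, c_relu)
            dh, grads[f"enc_{ax}_conv{i}_W"], grads[f"enc_{ax}_conv{i}_b"] = _conv_backward(
                dh, params[f"enc_{ax}_conv{i}_W"], c_conv, need_dx=(i > 0)
            )
    return grads


def forward(stack: np.ndarray, params: NetworkParams) -> ForwardTrace:
    """Score one observation stack; returns the full trace of encodings."""
    _check_stack(np.asarray(stack), params.arch, "forward")
    Q, cache = forward_batch(params, np.asarray(stack)[None])
    V = cache["V"]
    A = cache["A"]
    return ForwardTrace(
        t=cache["t"][0],
        T=cache["T"][0],
        T_bar=cache["T_bar"][0],
        s_bar=cache["s_bar"][0],
        V=float(V[0, 0]) if V is not None else None,
        A=A[0].copy() if A is not None else None,
        Q=Q[0].copy(),
    )


def dueling_aggregate(V: np.ndarray | float, A: np.ndarray) -> np.ndarray:
    """``Q_a = V + A_a - mean(A)``; hence ``mean(Q) = V`` exactly and Q is
    invariant to adding a constant to every advantage."""
    V = np.asarray(V, dtype=np.asarray(A).dtype)
    A = np.asarray(A)
    return V + A - A.mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# FLOPs accounting (1 multiply-accumulate = 1 FLOP)
# ---------------------------------------------------------------------------

def flops_breakdown(arch: ArchitectureSpec) -> list[tuple[str, int]]:
    """Per-layer MAC counts for one forward pass.

    Convention: one multiply-accumulate per conv/FC output element counts as
    one FLOP (``output_elements * kernel_volume * in_channels``); biases,
    activations and the dueling mean-subtraction are excluded.  The per-axis
    encoder cost is incurred once per plane pass, i.e. ``frames x 3`` times.
    """
    rows: list[tuple[str, int]] = []
    plane_passes = arch.frames * 3
    in_c = 1
    for i, (out_c, size) in enumerate(zip(arch.encoder_channels, arch.conv_sizes())):
        per_plane = size * size * out_c * arch.kernel * arch.kernel * in_c
        rows.append((f"encoder conv{i} ({in_c}->{out_c}, {size}x{size} out) x{plane_passes} planes", per_plane * plane_passes))
        in_c = out_c
    per_plane = arch.encoder_flat * arch.encoder_fc
    rows.append((f"encoder fc ({arch.encoder_flat}->{arch.encoder_fc}) x{plane_passes} planes", per_plane * plane_passes))
    rows.append(
        (
            f"local inference ({3 * arch.encoder_fc}->{arch.local_width}) x{arch.frames} frames",
            3 * arch.encoder_fc * arch.local_width * arch.frames,
        )
    )
    rows.append(
        (
            f"global inference ({arch.frames * arch.local_width}->{arch.global_width})",
            arch.frames * arch.local_width * arch.global_width,
        )
    )
    if arch.head_mode == "dueling":
        rows.append((f"value head ({arch.global_width}->1)", arch.global_width))
        rows.append((f"advantage head ({arch.global_width}->{N_ACTIONS})", arch.global_width * N_ACTIONS))
    else:
        rows.append((f"q head ({arch.global_width}->{N_ACTIONS})", arch.global_width * N_ACTIONS))
    return rows


def count_flops(arch: ArchitectureSpec) -> int:
    """Total MACs of one forward pass under the convention of :func:`flops_breakdown`."""
    return sum(f for _, f in flops_breakdown(arch))


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_params(params: NetworkParams, path: str | Path) -> None:
    """Self-describing checkpoint: JSON architecture header + parameter tensors."""
    buf = io.BytesIO()
    np.savez(buf, __arch__=np.frombuffer(params.arch.to_json().encode(), dtype=np.uint8), **params.arrays)
    Path(path).write_bytes(buf.getvalue())


def load_params(
    path: str | Path,
    arch: ArchitectureSpec | None = None,
    head_mode: str | None = None,
) -> NetworkParams:
    """Load a checkpoint; any supplied expectation (``arch``/``head_mode``)
    is checked against the stored architecture and mismatches raise."""
    with np.load(Path(path)) as data:
        stored = ArchitectureSpec.from_json(bytes(data["__arch__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__arch__"}
    if arch is not None and arch != stored:
        raise ConfigurationError(
            f"checkpoint architecture {stored} does not match expected {arch}"
        )
    if head_mode is not None and head_mode != stored.head_mode:
        raise ConfigurationError(
            f"checkpoint has head_mode={stored.head_mode!r}, cannot load as {head_mode!r}"
        )
    expected = set(stored.param_shapes())
    if set(arrays) != expected:
        raise ConfigurationError(
            f"checkpoint parameter names {sorted(arrays)} do not match architecture"
        )
    return NetworkParams(stored, arrays)
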