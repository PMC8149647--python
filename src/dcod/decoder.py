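"""Under-parameterized deep decoder network, with analytic gradients.

The decoder maps a *fixed* random tensor ``B0`` (shape k0 x n0 x n0) through
``d`` identical layers — twofold bilinear upsampling, a 1x1 convolution
(a pure channel mix ``w_i``), ReLU, and per-channel normalization with
learnable scale/shift — to a two-channel image: phase mapped to [0, 2*pi]
by ``2*pi*sigmoid`` and amplitude to [0, 1] by ``sigmoid``.  Because the 1x1
convolutions have no spatial extent, the network has fewer trainable scalars
than output pixels; this under-parameterization is itself the image prior.

The architecture is fixed and small, so forward and backward passes are
written directly in NumPy; gradients are exact (verified against finite
differences in the test suite) rather than produced by a general autodiff
framework.

Conventions: tensors are channel-first ``(k, h, w)``; bilinear upsampling
uses the half-pixel (corner-alignment off) convention with edge clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

from .wave_optics import ObjectField

__all__ = [
    "DecoderConfig",
    "DecoderState",
    "DecoderGrads",
    "init_state",
    "channel_normalize",
    "forward",
    "count_parameters",
    "fit_to_image",
    "save_state",
    "load_state",
]

CHANNEL_NORM_EPS = 1e-5


@dataclass(frozen=True)
class DecoderConfig:
    """Shape of the decoder.

    ``channels`` lists k_0 .. k_d (one entry more than ``depth``); the output
    layer maps k_d to ``output_channels`` without upsampling, so the output
    spatial size is ``input_size * upsample**depth``.
    """

    depth: int = 5
    channels: Tuple[int, ...] = (256,) * 6
    input_size: int = 16
    upsample: int = 2
    output_channels: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.channels) != self.depth + 1:
            raise ValueError(
                f"channels must list k_0..k_d ({self.depth + 1} entries), got {len(self.channels)}"
            )
        if any(k < 1 for k in self.channels):
            raise ValueError("all channel counts must be >= 1")
        if self.output_channels not in (1, 2):
            raise ValueError("output_channels must be 1 (phase only) or 2 (phase+amplitude)")
        if self.input_size < 1 or self.upsample < 1:
            raise ValueError("input_size and upsample must be positive")

    @property
    def output_size(self) -> int:
        return self.input_size * self.upsample**self.depth

    @classmethod
    def scaled(cls, input_size: int = 8, depth: int = 3, width: int = 64, output_channels: int = 2) -> "DecoderConfig":
        """Reduced configuration for desktop-scale runs (64x64 output by default)."""
        return cls(
            depth=depth,
            channels=(width,) * (depth + 1),
            input_size=input_size,
            output_channels=output_channels,
        )


@dataclass
class DecoderState:
    """Trainable parameters plus the fixed input tensor.

    ``base_input`` is never touched by the optimizer; everything else is.
    """

    config: DecoderConfig
    base_input: np.ndarray                 # (k0, n0, n0), fixed
    weights: List[np.ndarray]              # d matrices (k_i, k_{i+1})
    out_weight: np.ndarray                 # (k_d, output_channels)
    gammas: List[np.ndarray]               # d vectors (k_{i+1},)
    betas: List[np.ndarray]                # d vectors (k_{i+1},)

    def trainables(self) -> List[np.ndarray]:
        """Flat list of trainable arrays, in a stable order."""
        return [*self.weights, self.out_weight, *self.gammas, *self.betas]

    def copy(self) -> "DecoderState":
        return DecoderState(
            config=self.config,
            base_input=self.base_input.copy(),
            weights=[w.copy() for w in self.weights],
            out_weight=self.out_weight.copy(),
            gammas=[g.copy() for g in self.gammas],
            betas=[b.copy() for b in self.betas],
        )


@dataclass
class DecoderGrads:
    """Gradients matching DecoderState.trainables() order."""

    weights: List[np.ndarray]
    out_weight: np.ndarray
    gammas: List[np.ndarray]
    betas: List[np.ndarray]

    def trainables(self) -> List[np.ndarray]:
        return [*self.weights, self.out_weight, *self.gammas, *self.betas]


def init_state(config: DecoderConfig, seed: int) -> DecoderState:
    """Random initialization: B0 ~ N(0, 0.1^2); weights uniform fan-in scaled.

    The base tensor uses the 0.1 standard deviation of the reference
    training recipe; 1x1-conv weights draw from U(-1/sqrt(k_in), 1/sqrt(k_in)).
    The same seed reproduces the state bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    k = config.channels
    n0 = config.input_size
    base_input = rng.normal(0.0, 0.1, size=(k[0], n0, n0))
    weights = []
    for i in range(config.depth):
        bound = 1.0 / np.sqrt(k[i])
        weights.append(rng.uniform(-bound, bound, size=(k[i], k[i + 1])))
    bound = 1.0 / np.sqrt(k[-1])
    out_weight = rng.uniform(-bound, bound, size=(k[-1], config.output_channels))
    gammas = [np.ones(k[i + 1]) for i in range(config.depth)]
    betas = [np.zeros(k[i + 1]) for i in range(config.depth)]
    return DecoderState(config, base_input, weights, out_weight, gammas, betas)


def count_parameters(config: DecoderConfig) -> int:
    """Exact count of trainable scalars (excluding the fixed base tensor).

    Independent of the spatial sizes: 1x1 convolutions carry no spatial
    extent, which is what keeps the network under-parameterized.
    """
    k = config.channels
    n = sum(k[i] * k[i + 1] for i in range(config.depth))      # 1x1 convs
    n += sum(2 * k[i + 1] for i in range(config.depth))        # gamma + beta
    n += k[-1] * config.output_channels                        # output conv
    return n


@lru_cache(maxsize=32)
def _upsample_matrix(n: int) -> np.ndarray:
    """1-D twofold bilinear upsampling operator (2n x n), half-pixel, edge-clamped."""
    M = np.zeros((2 * n, n))
    for m in range(n):
        M[2 * m, max(m - 1, 0)] += 0.25
        M[2 * m, m] += 0.75
        M[2 * m + 1, m] += 0.75
        M[2 * m + 1, min(m + 1, n - 1)] += 0.25
    return M


def _upsample2(x: np.ndarray) -> np.ndarray:
    """(k, n, n) -> (k, 2n, 2n) separable bilinear upsampling."""
    M = _upsample_matrix(x.shape[1])
    y = np.einsum("ab,kbc->kac", M, x)
    return np.einsum("kac,dc->kad", y, M)


def _upsample2_adjoint(g: np.ndarray) -> np.ndarray:
    """Adjoint of _upsample2: (k, 2n, 2n) -> (k, n, n)."""
    M = _upsample_matrix(g.shape[1] // 2)
    y = np.einsum("ba,kbc->kac", M, g)
    return np.einsum("kac,cd->kad", y, M)


def channel_normalize(
    Z: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = CHANNEL_NORM_EPS
) -> np.ndarray:
    """Per-channel normalization ``(Z_j - mean(Z_j)) / (std(Z_j) + eps) * gamma_j + beta_j``.

    Statistics are empirical over the spatial positions of each channel
    (single-sample regime).  ``Z`` is channel-first ``(k, h, w)``;
    ``gamma``/``beta`` have shape ``(k,)``.  Constant channels are handled
    by the additive ``eps`` in the denominator.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    Z = np.asarray(Z, dtype=np.float64)
    mean = Z.mean(axis=(1, 2), keepdims=True)
    std = Z.std(axis=(1, 2), keepdims=True)
    y = (Z - mean) / (std + eps)
    return y * np.asarray(gamma)[:, None, None] + np.asarray(beta)[:, None, None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _ForwardCache:
    """Intermediate tensors kept for the backward pass."""

    __slots__ = ("x0", "pre_relu", "post_relu", "norm_ratio", "stds", "x_layers", "logits", "sig")

    def __init__(self) -> None:
        self.pre_relu: List[np.ndarray] = []
        self.post_relu: List[np.ndarray] = []
        self.norm_ratio: List[np.ndarray] = []
        self.stds: List[np.ndarray] = []
        self.x_layers: List[np.ndarray] = []


def _forward_impl(
    state: DecoderState, input_override: Optional[np.ndarray], keep_cache: bool
) -> Tuple[np.ndarray, np.ndarray, Optional[_ForwardCache]]:
    cfg = state.config
    x = state.base_input if input_override is None else np.asarray(input_override, dtype=np.float64)
    if x.shape != state.base_input.shape:
        raise ValueError(
            f"input override shape {x.shape} must match the base tensor {state.base_input.shape}"
        )
    cache = _ForwardCache() if keep_cache else None
    for i in range(cfg.depth):
        if cache is not None:
            cache.x_layers.append(x)
        u = _upsample2(x)
        pre = np.einsum("io,ixy->oxy", state.weights[i], u)
        post = np.maximum(pre, 0.0)
        mean = post.mean(axis=(1, 2), keepdims=True)
        std = post.std(axis=(1, 2), keepdims=True)
        ratio = (post - mean) / (std + CHANNEL_NORM_EPS)
        x = ratio * state.gammas[i][:, None, None] + state.betas[i][:, None, None]
        if cache is not None:
            cache.pre_relu.append(pre)
            cache.post_relu.append(post)
            cache.norm_ratio.append(ratio)
            cache.stds.append(std)
    logits = np.einsum("io,ixy->oxy", state.out_weight, x)
    sig = _sigmoid(logits)
    if cache is not None:
        cache.x_layers.append(x)
        cache.logits = logits
        cache.sig = sig
    phase = 2.0 * np.pi * sig[0]
    amplitude = sig[1] if cfg.output_channels == 2 else np.ones_like(phase)
    return phase, amplitude, cache


def forward(
    state: DecoderState,
    input_override: Optional[np.ndarray] = None,
    pitch_um: float = 1.12,
) -> ObjectField:
    """Decode the (possibly perturbed) input tensor into an object estimate.

    A pure function of ``(state, input_override)``: phase in [0, 2*pi] via
    ``2*pi*sigmoid``, amplitude in [0, 1] via ``sigmoid`` (all-ones when the
    configuration is phase-only).
    """
    phase, amplitude, _ = _forward_impl(state, input_override, keep_cache=False)
    return ObjectField(phase=phase, amplitude=amplitude, pitch_um=pitch_um)


def forward_with_cache(
    state: DecoderState, input_override: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray, _ForwardCache]:
    """Forward pass retaining intermediates for :func:`backward`."""
    phase, amplitude, cache = _forward_impl(state, input_override, keep_cache=True)
    return phase, amplitude, cache


def backward(
    state: DecoderState,
    cache: _ForwardCache,
    g_phase: np.ndarray,
    g_amplitude: Optional[np.ndarray],
) -> DecoderGrads:
    """Exact gradients of a scalar loss w.r.t. all trainable parameters.

    ``g_phase`` and ``g_amplitude`` are the loss gradients w.r.t. the decoded
    phase and amplitude images (``g_amplitude`` is ignored for phase-only
    configurations).
    """
    cfg = state.config
    sig = cache.sig
    g_sig = np.empty_like(sig)
    g_sig[0] = 2.0 * np.pi * np.asarray(g_phase)
    if cfg.output_channels == 2:
        if g_amplitude is None:
            g_amplitude = np.zeros_like(sig[1])
        g_sig[1] = np.asarray(g_amplitude)
    g_logits = g_sig * sig * (1.0 - sig)

    x_d = cache.x_layers[-1]
    g_out_weight = np.einsum("ixy,oxy->io", x_d, g_logits)
    g = np.einsum("io,oxy->ixy", state.out_weight, g_logits)

    g_weights: List[np.ndarray] = [None] * cfg.depth  # type: ignore[list-item]
    g_gammas: List[np.ndarray] = [None] * cfg.depth   # type: ignore[list-item]
    g_betas: List[np.ndarray] = [None] * cfg.depth    # type: ignore[list-item]
    for i in range(cfg.depth - 1, -1, -1):
        ratio = cache.norm_ratio[i]
        std = cache.stds[i]
        g_gammas[i] = np.einsum("kxy,kxy->k", g, ratio)
        g_betas[i] = g.sum(axis=(1, 2))
        gy = g * state.gammas[i][:, None, None]
        # backprop through (post - mean) / (std + eps) with empirical stats
        npix = ratio.shape[1] * ratio.shape[2]
        mean_gy = gy.mean(axis=(1, 2), keepdims=True)
        mean_gy_ratio = (gy * ratio).mean(axis=(1, 2), keepdims=True)
        std_safe = np.where(std > 0, std, np.inf)
        g_post = (gy - mean_gy) / (std + CHANNEL_NORM_EPS) - ratio * mean_gy_ratio / std_safe
        g_pre = g_post * (cache.pre_relu[i] > 0)
        u = _upsample2(cache.x_layers[i])
        g_weights[i] = np.einsum("ixy,oxy->io", u, g_pre)
        g_u = np.einsum("io,oxy->ixy", state.weights[i], g_pre)
        g = _upsample2_adjoint(g_u)
    return DecoderGrads(weights=g_weights, out_weight=g_out_weight, gammas=g_gammas, betas=g_betas)


def save_state(path, state: DecoderState) -> None:
    """Checkpoint a decoder state to a single ``.npz`` archive of named arrays."""
    cfg = state.config
    arrays = {
        "config_meta": np.array(
            [cfg.depth, cfg.input_size, cfg.upsample, cfg.output_channels], dtype=np.int64
        ),
        "config_channels": np.array(cfg.channels, dtype=np.int64),
        "base_input": state.base_input,
        "out_weight": state.out_weight,
    }
    for i in range(cfg.depth):
        arrays[f"weight_{i}"] = state.weights[i]
        arrays[f"gamma_{i}"] = state.gammas[i]
        arrays[f"beta_{i}"] = state.betas[i]
    np.savez(path, **arrays)


def load_state(path) -> DecoderState:
    """Restore a decoder state written by :func:`save_state`."""
    with np.load(path) as data:
        depth, input_size, upsample, out_ch = (int(v) for v in data["config_meta"])
        cfg = DecoderConfig(
            depth=depth,
            channels=tuple(int(k) for k in data["config_channels"]),
            input_size=input_size,
            upsample=upsample,
            output_channels=out_ch,
        )
        return DecoderState(
            config=cfg,
            base_input=data["base_input"],
            weights=[data[f"weight_{i}"] for i in range(depth)],
            out_weight=data["out_weight"],
            gammas=[data[f"gamma_{i}"] for i in range(depth)],
            betas=[data[f"beta_{i}"] for i in range(depth)],
        )


def fit_to_image(
    target: np.ndarray,
    config: DecoderConfig,
    iterations: int = 2000,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> Tuple[DecoderState, np.ndarray]:
    """Fit the decoder's amplitude channel to a target image by plain Adam.

    The deep-image-prior premise in isolation: no optical model, just
    ``mean((amplitude - target)^2)``.  Returns the trained state and the
    per-iteration loss history.
    """
    from .optim import AdamW  # local import to avoid a cycle at module load

    target = np.asarray(target, dtype=np.float64)
    if target.shape != (config.output_size, config.output_size):
        raise ValueError("target shape must match the decoder output size")
    state = init_state(config, seed)
    opt = AdamW(state.trainables(), learning_rate=learning_rate, weight_decay=0.0)
    losses = np.empty(iterations)
    npix = target.size
    for it in range(iterations):
        phase, amplitude, cache = forward_with_cache(state)
        resid = amplitude - target
        losses[it] = np.mean(resid**2)
        grads = backward(state, cache, g_phase=np.zeros_like(phase), g_amplitude=2.0 * resid / npix)
        opt.step(state.trainables(), grads.trainables())
    return state, losses
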