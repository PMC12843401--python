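"""Decoder: linear-complexity (performer) attention, multi-scale selective
attention (MSSA) and the merge-augment-upsample decoding path.

The decoder follows a progressive-fusion paradigm: at each stage the deep
feature map is bilinearly upsampled 2x, concatenated with the gated skip
feature (when one exists at that resolution), fused by a 3x3 convolution
and refined by MSSA. MSSA extracts context with four depthwise-separable
branches (kernels 3/5/7/9, each with ReLU and squeeze-and-excitation),
fuses them, and applies softmax-kernel random-feature attention over the
spatial tokens so that global context costs O(N*m*d) rather than O(N^2).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate, conv2d, upsample_bilinear
from .encoder import grid_to_seq, seq_to_grid

__all__ = [
    "performer_attention",
    "PerformerAttention",
    "SqueezeExcite",
    "MultiScaleSelectiveAttention",
    "DecoderStage",
    "SegmentationHead",
    "Decoder",
]


class NumericalStabilityError(FloatingPointError):
    """Raised when the kernel-feature normaliser degenerates to ~0."""


def _draw_projection(m: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian projections for ``m`` features in antithetic ± pairs."""
    return rng.normal(size=((m + 1) // 2, d))


def _log_features(x: np.ndarray, projection: np.ndarray, m: int) -> np.ndarray:
    """Log of the positive softmax-kernel feature map (without stabiliser).

    Features come in antithetic pairs ``exp(+w.x)``/``exp(-w.x)`` — each is
    individually an unbiased estimator of the softmax kernel (for inputs
    pre-scaled by ``d**-0.25``), and the pairing reduces the estimator
    variance. The ``-|x|^2/2`` term is the standard norm correction.
    """
    proj = x @ projection.T
    paired = np.concatenate([proj, -proj], axis=-1)[..., :m]
    return paired - 0.5 * np.sum(x**2, axis=-1, keepdims=True)


def performer_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                        m: int = 256, rng: np.random.Generator | None = None,
                        projection: np.ndarray | None = None,
                        eps: float = 1e-9) -> np.ndarray:
    """Kernel-approximated softmax attention, computed in O(N*m*d).

    ``q``, ``k``: (..., N, d); ``v``: (..., N, dv). The N x N attention
    matrix is never materialised: the output is
    ``D^-1 (phi(Q) (phi(K)^T V))`` with ``D = diag(phi(Q) phi(K)^T 1)``.
    Row weights implied by ``phi(Q) phi(K)^T`` therefore sum to one after
    normalisation by construction.
    """
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError("Q, K, V shapes are inconsistent")
    if m < 1:
        raise ValueError("number of random features m must be >= 1")
    d = q.shape[-1]
    if projection is None:
        rng = np.random.default_rng(0) if rng is None else rng
        projection = _draw_projection(m, d, rng)
    scale = d**-0.25
    qs, ks = q * scale, k * scale
    # per-query-row stabiliser for phi(Q), global one for phi(K): both cancel
    log_q = _log_features(qs, projection, m)
    log_k = _log_features(ks, projection, m)
    phi_q = np.exp(log_q - log_q.max(axis=-1, keepdims=True))
    phi_k = np.exp(log_k - log_k.max())
    kv = np.swapaxes(phi_k, -1, -2) @ v
    normaliser = phi_q @ np.sum(phi_k, axis=-2)[..., None]
    if np.any(normaliser <= eps):
        raise NumericalStabilityError("performer normaliser underflowed to zero")
    return (phi_q @ kv) / normaliser


class PerformerAttention(nn.Module):
    """Single-head linear attention over spatial tokens (differentiable).

    The random projection is drawn once at construction from a seedable
    generator and kept fixed, so the forward pass is deterministic.
    """

    def __init__(self, dim: int, num_features: int, rng: np.random.Generator):
        super().__init__()
        self.to_q = nn.Linear(dim, dim, rng)
        self.to_k = nn.Linear(dim, dim, rng)
        self.to_v = nn.Linear(dim, dim, rng)
        self.projection = Tensor(_draw_projection(num_features, dim, rng))
        self.num_features = num_features
        self.scale = dim**-0.25

    def _phi(self, x: Tensor, row_stabilize: bool) -> Tensor:
        from .autodiff import concatenate as cat

        xs = x * self.scale
        proj = xs @ self.projection.swapaxes(0, 1)
        paired = cat([proj, -proj], axis=-1)[..., : self.num_features]
        log = paired - (xs * xs).sum(axis=-1, keepdims=True) * 0.5
        if row_stabilize:
            shift = Tensor(log.data.max(axis=-1, keepdims=True))
        else:
            shift = Tensor(np.array(log.data.max()))
        return (log - shift).exp() * (1.0 / np.sqrt(self.num_features))

    def forward(self, tokens: Tensor) -> Tensor:
        q, k, v = self.to_q(tokens), self.to_k(tokens), self.to_v(tokens)
        phi_q = self._phi(q, row_stabilize=True)
        phi_k = self._phi(k, row_stabilize=False)
        kv = phi_k.swapaxes(-1, -2) @ v
        normaliser = phi_q @ phi_k.sum(axis=-2, keepdims=True).swapaxes(-1, -2)
        return (phi_q @ kv) / normaliser.clip_min(1e-9)


class SqueezeExcite(nn.Module):
    """Channel recalibration: global average pool -> bottleneck MLP ->
    per-channel sigmoid gates in (0,1)."""

    def __init__(self, channels: int, rng, reduction: int = 16, min_hidden: int = 4):
        super().__init__()
        hidden = max(min_hidden, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        B, C = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3)).reshape(B, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid().reshape(B, C, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class _DepthwiseSeparable(nn.Module):
    def __init__(self, channels: int, kernel: int, rng):
        super().__init__()
        self.depthwise = nn.Conv2d(channels, channels, kernel, rng,
                                   padding=kernel // 2, groups=channels, bias=False)
        self.pointwise = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class MultiScaleSelectiveAttention(nn.Module):
    """Four-branch multi-scale refinement with linear global attention.

    Branch k (kernels 3, 5, 7, 9): depthwise-separable conv -> ReLU -> SE.
    The concatenated 4C feature is fused to C channels by a 1x1 conv,
    refined by performer attention over the H*W spatial tokens, and the
    attention output is concatenated with the module input (2C) and
    projected back to C channels by a final 1x1 conv.
    """

    KERNELS = (3, 5, 7, 9)

    def __init__(self, channels: int, num_features: int, rng):
        super().__init__()
        self.branches = nn.ModuleList(
            _DepthwiseSeparable(channels, k, rng) for k in self.KERNELS
        )
        self.se_blocks = nn.ModuleList(
            SqueezeExcite(channels, rng) for _ in self.KERNELS
        )
        self.fuse = nn.Conv2d(len(self.KERNELS) * channels, channels, 1, rng)
        self.attention = PerformerAttention(channels, num_features, rng)
        self.out_proj = nn.Conv2d(2 * channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H == 0 or W == 0:
            raise ValueError("spatial size must be positive")
        outs = [se(branch(x).relu()) for branch, se in zip(self.branches, self.se_blocks)]
        fused = self.fuse(concatenate(outs, axis=1))
        tokens = self.attention(grid_to_seq(fused))
        attended = seq_to_grid(tokens, H, W)
        return self.out_proj(concatenate([attended, x], axis=1))


class DecoderStage(nn.Module):
    """One merge-augment-upsample step: bilinear 2x upsample, optional
    gated-skip concatenation, 3x3 fusion conv, and (on skip stages) MSSA."""

    def __init__(self, in_channels: int, skip_channels: int | None, out_channels: int,
                 num_features: int, rng, use_mssa: bool = True):
        super().__init__()
        total = in_channels + (skip_channels or 0)
        self.conv = nn.Conv2d(total, out_channels, 3, rng, padding=1)
        self.norm = nn.GroupNorm(nn.norm_groups(out_channels), out_channels)
        from .skip_gating import MultiKernelGate

        self.gate = MultiKernelGate(skip_channels, rng) if skip_channels else None
        self.mssa = (
            MultiScaleSelectiveAttention(out_channels, num_features, rng)
            if use_mssa else None
        )

    def forward(self, deep: Tensor, skip: Tensor | None = None) -> Tensor:
        B, C, H, W = deep.shape
        up = upsample_bilinear(deep, 2 * H, 2 * W)
        if self.gate is not None:
            if skip is None:
                raise ValueError("stage expects a skip feature but none was given")
            if skip.shape[2:] != (2 * H, 2 * W):
                raise ValueError(
                    f"skip spatial size {skip.shape[2:]} must be twice the deep "
                    f"feature size {(H, W)}"
                )
            up = concatenate([up, self.gate(skip)], axis=1)
        elif skip is not None:
            raise ValueError("stage was built without a skip connection")
        h = self.norm(self.conv(up)).relu()
        if self.mssa is not None:
            h = self.mssa(h)
        return h


class SegmentationHead(nn.Module):
    """1x1 convolution to per-class logits (no activation)."""

    def __init__(self, in_channels: int, num_classes: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class Decoder(nn.Module):
    """Neck convolution + chained decoder stages restoring full resolution."""

    def __init__(self, config, skip_channels: tuple, rng):
        super().__init__()
        dc = config.decoder_channels
        self.config = config
        self.neck = nn.Conv2d(config.hidden_dim, dc[0], 3, rng, padding=1)
        self.neck_norm = nn.GroupNorm(nn.norm_groups(dc[0]), dc[0])
        # skips ordered deepest-first (1/8, 1/4, 1/2) to match stage order
        deep_first = (skip_channels[2], skip_channels[1], skip_channels[0])
        active = set(config.skip_stages[: config.num_skips])
        self.stage_skip: list[int | None] = []
        stages = []
        prev = dc[0]
        for t in range(config.num_up_stages):
            sk = None
            if t in active:
                sk = deep_first[config.skip_stages.index(t)]
            stages.append(
                DecoderStage(prev, sk, dc[t], config.performer_features, rng,
                             use_mssa=sk is not None)
            )
            self.stage_skip.append(sk)
            prev = dc[t]
        self.stages = nn.ModuleList(stages)

    def forward(self, seq: Tensor, skips: tuple) -> Tensor:
        g = self.config.grid_size
        h = self.neck_norm(self.neck(seq_to_grid(seq, g, g))).relu()
        deep_first = (skips[2], skips[1], skips[0])
        for t, stage in enumerate(self.stages):
            skip = None
            if self.stage_skip[t] is not None:
                skip = deep_first[self.config.skip_stages.index(t)]
            h = stage(h, skip)
        return h
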