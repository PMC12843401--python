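"""Hybrid encoder: convolutional stem, patch embedding, multi-scale gate
attention (MSGA) and Manhattan-biased multi-head self-attention (ME-MSA).

The encoder is the transformer half of a U-shaped hybrid: a residual CNN
stem extracts features at 1/2, 1/4 and 1/8 resolution (kept as skip
connections), the 1/8 feature map is patch-embedded into a token sequence,
and a stack of ``depth`` blocks refines the sequence. Each block routes the
tokens through MSGA (as a spatial grid), layer norm, distance-biased
self-attention, a second layer norm and an MLP, with residual connections
around the attention and MLP sub-blocks.

The attention bias implements a locality prior: attention logits between
tokens i and j are penalised by ``lambda * D_ij`` where ``D_ij`` is the
Manhattan distance between their grid coordinates normalised by
``H + W``, and ``lambda`` is a learnable per-head scalar initialised to 1.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate, softmax
from .config import ConfigurationError, ModelConfig

__all__ = [
    "manhattan_bias",
    "seq_to_grid",
    "grid_to_seq",
    "ConvStem",
    "PatchEmbed",
    "ManhattanSelfAttention",
    "MultiScaleGateAttention",
    "EncoderBlock",
    "Encoder",
]


def manhattan_bias(grid_h: int, grid_w: int) -> np.ndarray:
    """Normalised Manhattan-distance matrix over a token grid.

    Tokens are enumerated row-major from the top-left, 0-based. Entry
    ``(i, j)`` is ``(|x_i - x_j| + |y_i - y_j|) / (grid_h + grid_w)``,
    hence symmetric with a zero diagonal and values in ``[0, 1)``.
    """
    if grid_h < 1 or grid_w < 1:
        raise ValueError("grid dimensions must be >= 1")
    rows, cols = np.divmod(np.arange(grid_h * grid_w), grid_w)
    d = np.abs(rows[:, None] - rows[None, :]) + np.abs(cols[:, None] - cols[None, :])
    return d.astype(np.float64) / float(grid_h + grid_w)


def seq_to_grid(x: Tensor, grid_h: int, grid_w: int) -> Tensor:
    """(B, N, D) token sequence -> (B, D, H, W) feature grid (row-major)."""
    B, N, D = x.shape
    if N != grid_h * grid_w:
        raise ValueError(f"sequence length {N} does not match grid {grid_h}x{grid_w}")
    return x.transpose(0, 2, 1).reshape(B, D, grid_h, grid_w)


def grid_to_seq(x: Tensor) -> Tensor:
    """(B, C, H, W) feature grid -> (B, H*W, C) token sequence (row-major)."""
    B, C, H, W = x.shape
    return x.reshape(B, C, H * W).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# CNN stem
# ---------------------------------------------------------------------------

class _ResidualBlock(nn.Module):
    """Two 3x3 convs with group norm; optional stride-2 downsampling."""

    def __init__(self, cin: int, cout: int, rng, stride: int = 1):
        super().__init__()
        gn = lambda c: nn.GroupNorm(nn.norm_groups(c), c)
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, padding=1, bias=False)
        self.norm1 = gn(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1, bias=False)
        self.norm2 = gn(cout)
        self.shortcut = (
            nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            if stride != 1 or cin != cout else None
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        s = x if self.shortcut is None else self.shortcut(x)
        return (h + s).relu()


class ConvStem(nn.Module):
    """Residual convolutional backbone emitting skips at 1/2, 1/4, 1/8.

    Stage widths are ``w, 2w, 4w`` for ``w = stem_width``.
    """

    def __init__(self, in_channels: int, width: int, rng):
        super().__init__()
        w = width
        self.entry = nn.Conv2d(in_channels, w, 3, rng, padding=1, bias=False)
        self.entry_norm = nn.GroupNorm(nn.norm_groups(w), w)
        self.stage1 = _ResidualBlock(w, w, rng, stride=2)        # 1/2
        self.stage2 = _ResidualBlock(w, 2 * w, rng, stride=2)    # 1/4
        self.stage3 = _ResidualBlock(2 * w, 4 * w, rng, stride=2)  # 1/8
        self.skip_channels = (w, 2 * w, 4 * w)  # at 1/2, 1/4, 1/8

    def forward(self, x: Tensor):
        h = self.entry_norm(self.entry(x)).relu()
        s1 = self.stage1(h)
        s2 = self.stage2(s1)
        s3 = self.stage3(s2)
        return s3, (s1, s2, s3)


class PatchEmbed(nn.Module):
    """Flatten-and-project: the 1/8-resolution stem features are projected
    to the hidden dimension with a strided convolution so that the token
    grid has ``input_size / patch_size`` cells per side, then flattened
    row-major into a sequence. A learnable position embedding is added."""

    def __init__(self, config: ModelConfig, in_channels: int, rng):
        super().__init__()
        stride = config.patch_size // 8
        self.grid = (config.grid_size, config.grid_size)
        self.proj = nn.Conv2d(in_channels, config.hidden_dim, stride, rng, stride=stride)
        n = config.grid_size**2
        self.pos_embed = nn.Parameter(rng.normal(0.0, 0.02, size=(1, n, config.hidden_dim)))

    def forward(self, feats: Tensor) -> Tensor:
        grid = self.proj(feats)
        if grid.shape[2:] != self.grid:
            raise ValueError(
                f"feature grid {grid.shape[2:]} does not match token grid {self.grid}"
            )
        return grid_to_seq(grid) + self.pos_embed


# ---------------------------------------------------------------------------
# ME-MSA
# ---------------------------------------------------------------------------

class ManhattanSelfAttention(nn.Module):
    """Multi-head self-attention with a learnable Manhattan-distance penalty.

    Per head h: ``Attn = softmax(Q K^T / sqrt(d_k) - lambda_h * D) V`` with
    ``D`` the normalised Manhattan-distance matrix of the token grid and
    ``lambda_h`` a learnable scalar (init ``lambda_init``). With all
    ``lambda_h = 0`` the layer is exactly vanilla multi-head attention.
    """

    def __init__(self, dim: int, num_heads: int, rng, lambda_init: float = 1.0):
        super().__init__()
        if dim % num_heads:
            raise ConfigurationError(f"hidden_dim={dim} not divisible by num_heads={num_heads}")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.lam = nn.Parameter(np.full(num_heads, float(lambda_init)))

    def forward(self, x: Tensor, grid_shape: tuple) -> Tensor:
        B, N, D = x.shape
        gh, gw = grid_shape
        if gh * gw != N:
            raise ValueError(f"bias grid {grid_shape} does not match sequence length {N}")
        H, dk = self.num_heads, self.head_dim
        qkv = self.qkv(x).reshape(B, N, 3, H, dk).transpose(2, 0, 3, 1, 4)  # 3,B,H,N,dk
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
        dist = Tensor(manhattan_bias(gh, gw))  # constant N x N
        bias = self.lam.reshape(1, H, 1, 1) * dist  # broadcast to B,H,N,N
        attn = softmax(logits - bias, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


# ---------------------------------------------------------------------------
# MSGA
# ---------------------------------------------------------------------------

class MultiScaleGateAttention(nn.Module):
    """Grouped cascade of depthwise convolution, directional-pooling spatial
    gating and cross-spatial interaction.

    The C channels are split into G groups. Per group g (c = C/G channels):

    1. ``F_dw = DWConv3x3(X_g)`` — fine local structure.
    2. Directional pooling: average- and max-pooled strips along each axis
       are concatenated channel-wise and reduced to one channel by a 1x1
       convolution shared between the two directions; the two strips are
       broadcast-added and squashed: ``M_sp = sigmoid(h_strip + w_strip)``.
    3. ``F_gated = F_dw * M_sp``.
    4. Cross-spatial interaction: a group-normalised stream and a
       channel-softmaxed global-average descriptor exchange information via
       matrix products in both pairings; the two 1 x (H*W) maps are summed,
       squashed by a sigmoid and re-weight the *original* group input:
       ``Y_g = X_g * sigmoid(CrossSpatial(F_gated))``.

    Because the final gate is a sigmoid in (0,1), the block can attenuate
    but never amplify: ``|Y| <= |X|`` elementwise.
    """

    def __init__(self, channels: int, groups: int, rng):
        super().__init__()
        if channels % groups:
            raise ConfigurationError(
                f"channels={channels} not divisible by msga_groups={groups}"
            )
        self.groups = groups
        self.group_ch = channels // groups
        self.dwconv = nn.Conv2d(channels, channels, 3, rng, padding=1,
                                groups=channels, bias=False)
        # shared 1x1 reduction for directional pooling: per group 2c -> 1
        self.pool_reduce = nn.Conv2d(2 * channels, groups, 1, rng, groups=groups)
        gn_groups = math.gcd(groups, self.group_ch)
        self.cross_norm = nn.GroupNorm(gn_groups, self.group_ch)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        G, c = self.groups, self.group_ch
        if C != G * c:
            raise ValueError(f"expected {G * c} channels, got {C}")

        f_dw = self.dwconv(x)

        # directional pooling: strips along each axis, avg & max interleaved
        # per group so the grouped 1x1 conv sees [avg_g, max_g] in group g.
        def strips(axis: int) -> Tensor:
            avg = x.mean(axis=axis, keepdims=True)
            mx = x.max(axis=axis, keepdims=True)
            both = concatenate(
                [avg.reshape(B, G, c, *avg.shape[2:]), mx.reshape(B, G, c, *mx.shape[2:])],
                axis=2,
            )
            return both.reshape(B, 2 * C, *avg.shape[2:])

        h_strip = self.pool_reduce(strips(3))  # B,G,H,1
        w_strip = self.pool_reduce(strips(2))  # B,G,1,W
        m_sp = (h_strip + w_strip).sigmoid()   # B,G,H,W
        f_gated = (f_dw.reshape(B, G, c, H, W) *
                   m_sp.reshape(B, G, 1, H, W)).reshape(B, C, H, W)

        # cross-spatial interaction, groups folded into the batch axis
        fg = f_gated.reshape(B * G, c, H, W)
        normed = self.cross_norm(fg)
        a_norm = normed.reshape(B * G, c, H * W)
        a_raw = fg.reshape(B * G, c, H * W)
        b_raw = softmax(a_raw.mean(axis=2, keepdims=True).transpose(0, 2, 1), axis=-1)
        b_norm = softmax(a_norm.mean(axis=2, keepdims=True).transpose(0, 2, 1), axis=-1)
        cross = b_raw @ a_norm + b_norm @ a_raw       # (B*G, 1, H*W)
        gate = cross.sigmoid().reshape(B, G, 1, H, W)
        y = x.reshape(B, G, c, H, W) * gate
        return y.reshape(B, C, H, W)


# ---------------------------------------------------------------------------
# encoder block and stack
# ---------------------------------------------------------------------------

class EncoderBlock(nn.Module):
    """One hybrid encoder layer.

    ``Y1 = X + MEMSA(LN(seq(MSGA(grid(X)))))``;
    ``Y2 = Y1 + MLP(LN(Y1))``.
    The residual source of the attention sub-block is the block input X.
    """

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        D = config.hidden_dim
        self.msga = MultiScaleGateAttention(D, config.msga_groups, rng)
        self.norm1 = nn.LayerNorm(D)
        self.attn = ManhattanSelfAttention(D, config.num_heads, rng, config.lambda_init)
        self.norm2 = nn.LayerNorm(D)
        self.mlp = nn.MLP(D, config.mlp_dim, rng)

    def forward(self, x: Tensor, grid_shape: tuple) -> Tensor:
        gh, gw = grid_shape
        gated = grid_to_seq(self.msga(seq_to_grid(x, gh, gw)))
        y1 = x + self.attn(self.norm1(gated), grid_shape)
        return y1 + self.mlp(self.norm2(y1))


class Encoder(nn.Module):
    """Stem + patch embedding + ``depth`` encoder blocks."""

    def __init__(self, config: ModelConfig, in_channels: int, rng):
        super().__init__()
        self.config = config
        self.stem = ConvStem(in_channels, config.stem_width, rng)
        self.embed = PatchEmbed(config, self.stem.skip_channels[-1], rng)
        self.blocks = nn.ModuleList(
            EncoderBlock(config, rng) for _ in range(config.depth)
        )
        self.norm = nn.LayerNorm(config.hidden_dim)

    def forward(self, x: Tensor):
        feats, skips = self.stem(x)
        seq = self.embed(feats)
        g = (self.config.grid_size, self.config.grid_size)
        for block in self.blocks:
            seq = block(seq, g)
        return self.norm(seq), skips
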