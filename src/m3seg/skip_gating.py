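"""Multi-kernel gated attention gate (MKGAG) for skip connections.

Skip features carry fine spatial detail but also low-level noise. Before a
skip is fused into the decoder it is filtered by an ensemble-style gate:
three independent 3x3 group-convolution branches (each followed by batch
normalisation) are summed, passed through ReLU6, compressed to a single
channel by a 1x1 convolution and squashed by a sigmoid. The resulting
spatial attention map ``A`` (one channel, values in (0,1)) re-weights the
input: ``Y = X * A`` broadcast over channels. The gate therefore attenuates
but never amplifies, and modulates every channel identically.

Unlike classic attention gates, the module consumes only the skip feature
itself — no decoder-side gating signal.
"""

from __future__ import annotations

import math

from . import nn
from .autodiff import Tensor
from .config import ConfigurationError

__all__ = ["MultiKernelGate"]


class MultiKernelGate(nn.Module):
    """Three-branch 3x3 group-conv gate producing a shared spatial map.

    Parameters
    ----------
    channels : number of skip-feature channels C.
    conv_groups : group count of the 3x3 convolutions; defaults to
        ``gcd(4, C)``.
    bn_identity : run batch norms in deterministic identity mode
        (affine-only pass-through) — used for reproducible fixtures.
    """

    NUM_BRANCHES = 3

    def __init__(self, channels: int, rng, conv_groups: int | None = None,
                 bn_identity: bool = False):
        super().__init__()
        groups = math.gcd(4, channels) if conv_groups is None else conv_groups
        if channels % groups:
            raise ConfigurationError(
                f"channels={channels} not divisible by conv_groups={groups}"
            )
        self.branches = nn.ModuleList(
            nn.Conv2d(channels, channels, 3, rng, padding=1, groups=groups)
            for _ in range(self.NUM_BRANCHES)
        )
        self.norms = nn.ModuleList(
            nn.BatchNorm2d(channels, identity=bn_identity)
            for _ in range(self.NUM_BRANCHES)
        )
        self.squeeze = nn.Conv2d(channels, 1, 1, rng)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        return [norm(conv(x)) for conv, norm in zip(self.branches, self.norms)]

    def attention_map(self, x: Tensor) -> Tensor:
        hs = self.branch_outputs(x)
        fused = hs[0] + hs[1] + hs[2]
        return self.squeeze(fused.relu6()).sigmoid()  # (B, 1, H, W)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)
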