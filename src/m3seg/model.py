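"""Whole-model assembly: encoder -> gated skips -> decoder -> head.

``build_model`` wires the hybrid U-shaped network from a
:class:`~m3seg.config.ModelConfig`; the forward pass maps a
``(B, channels, S, S)`` image batch to ``(B, num_classes, S, S)`` logits.
Every operator in the graph is differentiable, so one total-loss backward
pass reaches all trainable parameters.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor
from .config import ModelConfig
from .decoder import Decoder, SegmentationHead
from .encoder import Encoder

__all__ = ["SegmentationModel", "build_model", "sequence_length", "count_parameters"]


def sequence_length(input_size: int, patch_size: int) -> int:
    """Number of tokens for a square input: ``(input_size / patch_size)**2``.

    224-px inputs give 49 tokens at 32-px patches, 196 at 16 and 784 at 8.
    """
    if patch_size <= 0 or input_size % patch_size:
        raise ValueError(
            f"input_size={input_size} is not divisible by patch_size={patch_size}"
        )
    return (input_size // patch_size) ** 2


class SegmentationModel(nn.Module):
    def __init__(self, config: ModelConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.in_channels = in_channels
        self.encoder = Encoder(config, in_channels, rng)
        self.decoder = Decoder(config, self.encoder.stem.skip_channels, rng)
        self.head = SegmentationHead(config.decoder_channels[-1], config.num_classes, rng)

    def forward(self, images: Tensor | np.ndarray) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
        S = self.config.input_size
        if x.ndim != 4 or x.shape[2] != S or x.shape[3] != S:
            raise ValueError(
                f"expected input of shape (B, {self.in_channels}, {S}, {S}), got {x.shape}"
            )
        seq, skips = self.encoder(x)
        feats = self.decoder(seq, skips)
        return self.head(feats)

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, (B, C, S, S), inference mode."""
        from .autodiff import no_grad, softmax

        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(images)
                probs = softmax(logits.swapaxes(1, 3), axis=-1).swapaxes(1, 3)
        finally:
            self.train(was_training)
        return probs.data

    def predict_mask(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_probs(images), axis=1).astype(np.int64)


def build_model(config: ModelConfig, in_channels: int = 3,
                seed: int = 0) -> SegmentationModel:
    """Construct the segmentation network with seeded initialisation.

    ``seed`` drives both weight initialisation and the (fixed) kernel
    feature draw of the linear-attention layers, so two builds with the
    same seed are identical.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D3]))
    return SegmentationModel(config, in_channels, rng)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars reachable from the model."""
    return int(sum(p.data.size for p in model.parameters()))


def parameter_breakdown(model: nn.Module) -> dict[str, int]:
    """Per-top-level-submodule trainable-parameter counts."""
    counts: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        counts[top] = counts.get(top, 0) + p.data.size
    return counts
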