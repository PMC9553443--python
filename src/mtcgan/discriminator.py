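"""Convolutional discriminator with differentiated conditional input.

Seven 1-D convolutional layers, each followed by layer normalisation and
LeakyReLU, score a label sequence for authenticity.  The main input is a
label score sequence (one-hot for real labels, softmaxed generator scores
for fakes); the conditional input is always the real label sequence L,
spliced channel-wise with the main input before the first convolution.  A
masked global average pool and a sigmoid produce one score in (0, 1) per
sentence.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .config import ModelConfig
from .nn import Conv1d, LayerNorm, Linear, Module

__all__ = ["Discriminator"]


class Discriminator(Module):
    def __init__(self, n_tags: int, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.disc_channels
        n_layers = cfg.disc_layers
        chans = [2 * n_tags] + [c] * n_layers
        self.convs = [
            Conv1d(chans[i], chans[i + 1], 3, rng, padding=1) for i in range(n_layers)
        ]
        self.lns = [LayerNorm(c) for _ in range(n_layers)]
        self.out = Linear(c, 1, rng)

    def __call__(
        self, label_feats: Tensor, condition: Tensor, mask: np.ndarray
    ) -> Tensor:
        """label_feats, condition: (B, T, n_tags); returns scores (B,) in (0,1)."""
        if label_feats.shape != condition.shape:
            raise ValueError("label features and condition must be aligned")
        m = Tensor(np.asarray(mask, float)[:, :, None])
        x = concat([label_feats * m, condition * m], axis=-1).transpose(0, 2, 1)
        mask_c = Tensor(np.asarray(mask, float)[:, None, :])
        for conv, ln in zip(self.convs, self.lns):
            x = conv(x) * mask_c  # keep padding silent between layers
            x = ln(x.transpose(0, 2, 1)).transpose(0, 2, 1).leaky_relu(0.2) * mask_c
        lengths = np.asarray(mask, float).sum(axis=1)  # (B,)
        pooled = x.sum(axis=2) * Tensor(1.0 / lengths[:, None])  # (B, C)
        return self.out(pooled).sigmoid().reshape(-1)
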