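"""Multigranularity text feature encoders.

Four encoders extract complementary views of a character sequence:

* character granularity (CGFE): two stacked GRU layers track relative
  position information between characters; a fully connected layer with tanh
  yields per-position features h_c in (-1, 1);
* sentence granularity (SGFE): a 6-layer Transformer-style encoder with
  8-head self-attention; exports both the 6th layer's attention output a_6
  (the "attention data") and its contextual output h_6;
* paragraph granularity (PGFE): same architecture with independent
  parameters, run over the concatenated characters of a paragraph so that
  attention spans sentence boundaries;
* chapter granularity (AGFE): three 1-D convolutions, global max pooling and
  a fully connected layer summarise a whole chapter as one core-feature
  vector h_a.

The attention data of the sentence and paragraph encoders are spliced per
position (:func:`fuse_attention`) to form the generator's main input,
replacing the white noise a conditional GAN would otherwise consume.

The encoder block follows the printed recipe
``h = LN(LN(a + f) + Linear(LN(a + f)))`` by default (it normalises before
the feed-forward and omits the canonical inner residual around attention);
set ``encoder_block="canonical"`` for the standard Transformer block.
Positional encodings are off by default — the GRU branch is the positional
mechanism — but sinusoidal encodings can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, masked_softmax
from .nn import Conv1d, Dropout, Embedding, GRUCell, LayerNorm, Linear, Module

__all__ = [
    "MtfeConfig",
    "gru_step",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "EncoderLayer",
    "TransformerEncoder",
    "CGFE",
    "SGFE",
    "AGFE",
    "fuse_attention",
    "sinusoidal_encoding",
]


@dataclass
class MtfeConfig:
    d_model: int = 128
    gru_hidden: int = 64
    article_dim: int = 64
    n_layers: int = 6
    n_heads: int = 8
    dropout: float = 0.3
    encoder_block: str = "paper"  # "paper" | "canonical"
    positional_encoding: str = "none"  # "none" | "sinusoidal"
    granularities: tuple[str, ...] = ("char", "sentence", "paragraph", "chapter")

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.encoder_block not in ("paper", "canonical"):
            raise ValueError(f"unknown encoder_block {self.encoder_block!r}")
        if self.positional_encoding not in ("none", "sinusoidal"):
            raise ValueError(f"unknown positional_encoding {self.positional_encoding!r}")
        unknown = set(self.granularities) - {"char", "sentence", "paragraph", "chapter"}
        if unknown:
            raise ValueError(f"unknown granularities {sorted(unknown)}")
        if not ({"sentence", "paragraph"} & set(self.granularities)):
            raise ValueError("at least one of sentence/paragraph granularity required")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def gru_step(cell: GRUCell, e: Tensor, p_prev: Tensor) -> Tensor:
    """One reset/update-gated recurrence step (see :class:`mtcgan.nn.GRUCell`)."""
    return cell(e, p_prev)


def sinusoidal_encoding(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def scaled_dot_attention(
    q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None
) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / sqrt(d_k)) V with key-side masking.

    q, k, v: (..., T, d_k); mask: boolean (..., T) key validity (broadcastable).
    Returns (Z, attention weights).  Raises on an all-masked row.
    """
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    key_mask = None
    if mask is not None:
        key_mask = np.asarray(mask, dtype=bool)[..., None, :]
    weights = masked_softmax(scores, key_mask)
    return weights @ v, weights


class MultiHeadAttention(Module):
    """8-way multihead self-attention; heads are parallel d_k-dimensional
    projections whose outputs are concatenated and mixed by W_O."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.wq = Linear(d_model, d_model, rng, bias=False)
        self.wk = Linear(d_model, d_model, rng, bias=False)
        self.wv = Linear(d_model, d_model, rng, bias=False)
        self.wo = Linear(d_model, d_model, rng, bias=False)
        self.n_heads = n_heads
        self.d_model = d_model

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h = self.n_heads
        return x.reshape(b, t, h, d // h).transpose(0, 2, 1, 3)

    def __call__(self, e: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, t, d = e.shape
        q, k, v = self._split(self.wq(e)), self._split(self.wk(e)), self._split(self.wv(e))
        head_mask = None
        if mask is not None:
            head_mask = np.asarray(mask, dtype=bool)[:, None, :]  # (B, 1, T)
        z, _ = scaled_dot_attention(q, k, v, head_mask)
        z = z.transpose(0, 2, 1, 3).reshape(b, t, d)
        out = self.wo(z)
        if mask is not None:
            out = out * Tensor(np.asarray(mask, float)[:, :, None])
        return out


class EncoderLayer(Module):
    """One encoding layer combining attention data a with carry-in f."""

    def __init__(self, d_model: int, rng: np.random.Generator, block: str = "paper"):
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.block = block
        if block == "paper":
            self.linear = Linear(d_model, d_model, rng)
        else:  # canonical 2-layer feed-forward
            self.ff1 = Linear(d_model, 4 * d_model, rng)
            self.ff2 = Linear(4 * d_model, d_model, rng)

    def __call__(self, a: Tensor, f: Tensor) -> Tensor:
        if self.block == "paper":
            u = self.ln1(a + f)
            return self.ln2(u + self.linear(u))
        u = self.ln1(a + f)
        return self.ln2(u + self.ff2(self.ff1(u).relu()))


class TransformerEncoder(Module):
    """Stack of identical encoding layers; returns the last layer's attention
    output a_L and contextual output h_L."""

    def __init__(self, cfg: MtfeConfig, rng: np.random.Generator):
        self.attn = [
            MultiHeadAttention(cfg.d_model, cfg.n_heads, rng) for _ in range(cfg.n_layers)
        ]
        self.layers = [
            EncoderLayer(cfg.d_model, rng, cfg.encoder_block) for _ in range(cfg.n_layers)
        ]
        self.drops = [Dropout(cfg.dropout, rng) for _ in range(cfg.n_layers)]

    def __call__(
        self, e: Tensor, mask: np.ndarray | None = None
    ) -> tuple[Tensor, Tensor]:
        f = e
        a = None
        for attn, layer, drop in zip(self.attn, self.layers, self.drops):
            a = attn(f, mask)
            f = drop(layer(a, f))
        if mask is not None:
            m = Tensor(np.asarray(mask, float)[:, :, None])
            a, f = a * m, f * m
        return a, f

    def set_training(self, training: bool) -> None:
        for d in self.drops:
            d.training = training


class CGFE(Module):
    """Character-granularity encoder: embedding -> 2 GRU layers -> FC -> tanh."""

    def __init__(self, vocab_size: int, cfg: MtfeConfig, rng: np.random.Generator,
                 emb: Embedding | None = None):
        self.emb = emb if emb is not None else Embedding(vocab_size, cfg.d_model, rng)
        self.gru1 = GRUCell(cfg.d_model, cfg.gru_hidden, rng)
        self.gru2 = GRUCell(cfg.gru_hidden, cfg.gru_hidden, rng)
        self.fc = Linear(cfg.gru_hidden, cfg.d_model, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.gru_hidden = cfg.gru_hidden

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        b, t = ids.shape
        e = self.drop(self.emb(ids))  # (B, T, d)
        outs1 = self._run(self.gru1, e, b, t)
        outs2 = self._run(self.gru2, outs1, b, t)
        h = self.fc(outs2).tanh()
        return h * Tensor(np.asarray(mask, float)[:, :, None])

    def _run(self, cell: GRUCell, seq: Tensor, b: int, t: int) -> Tensor:
        p = Tensor(np.zeros((b, cell.d_hidden)))
        steps = []
        for i in range(t):
            p = cell(seq[:, i, :], p)
            steps.append(p.reshape(b, 1, cell.d_hidden))
        return concat(steps, axis=1)

    def set_training(self, training: bool) -> None:
        self.drop.training = training


class SGFE(Module):
    """Sentence (or paragraph) granularity encoder: embedding + Transformer
    stack; outputs (attention data a_6, contextual features h_6)."""

    def __init__(self, vocab_size: int, cfg: MtfeConfig, rng: np.random.Generator,
                 emb: Embedding | None = None):
        self.emb = emb if emb is not None else Embedding(vocab_size, cfg.d_model, rng)
        self.encoder = TransformerEncoder(cfg, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.positional = cfg.positional_encoding

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        e = self.emb(ids)
        if self.positional == "sinusoidal":
            b, t = ids.shape
            e = e + Tensor(sinusoidal_encoding(t, e.shape[-1])[None])
        e = self.drop(e)
        return self.encoder(e, mask)

    def set_training(self, training: bool) -> None:
        self.drop.training = training
        self.encoder.set_training(training)


class AGFE(Module):
    """Article (chapter) granularity encoder: 3 x conv1d + ReLU, global max
    pooling, fully connected layer with dropout."""

    KERNEL = 3

    def __init__(self, vocab_size: int, cfg: MtfeConfig, rng: np.random.Generator,
                 emb: Embedding | None = None):
        d = cfg.d_model
        self.emb = emb if emb is not None else Embedding(vocab_size, d, rng)
        self.conv1 = Conv1d(d, d, self.KERNEL, rng, padding=1)
        self.conv2 = Conv1d(d, d, self.KERNEL, rng, padding=1)
        self.conv3 = Conv1d(d, cfg.article_dim, self.KERNEL, rng, padding=1)
        self.fc = Linear(cfg.article_dim, cfg.article_dim, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.article_dim = cfg.article_dim

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.size == 0:
            raise ValueError("chapter is empty")
        if ids.size < self.KERNEL:  # pad to the receptive field
            ids = np.pad(ids, (0, self.KERNEL - ids.size))
        e = self.emb(ids[None, :])  # (1, T, d)
        x = e.transpose(0, 2, 1)  # channels first
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = self.conv3(x).relu()
        pooled = x.max(axis=2)  # (1, article_dim) global max pool
        return self.drop(self.fc(pooled)).reshape(self.article_dim)

    def set_training(self, training: bool) -> None:
        self.drop.training = training


def fuse_attention(a_s: Tensor, a_p: Tensor) -> Tensor:
    """Per-position splice [a_s || a_p] — the generator's main input."""
    if a_s.shape[:-1] != a_p.shape[:-1]:
        raise ValueError(f"length mismatch: {a_s.shape} vs {a_p.shape}")
    return concat([a_s, a_p], axis=-1)
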