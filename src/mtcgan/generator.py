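"""The conditionally enhanced U-Net generator.

The generator composes the multigranularity encoders with a 1-D U-Net over a
seed pseudo-sequence:

* LSFE (label seed feature encoder): the flat entity-distribution seed is
  projected and reshaped to a length-64 pseudo-sequence, then passed through
  6 stride-2 convolution levels (conv + layer norm + ReLU; tanh at level 6),
  halving the length at every level and exporting each level's feature map as
  a skip connection;
* MGFFL (multigranularity feature fusion layer): per text position, the
  character/sentence/paragraph features, the broadcast chapter feature and
  the projected U-Net bottom are spliced and projected to the condition Y
  (sentence and paragraph features are first projected to a common width and
  added element-wise — the contraposition addition);
* FALG decoder: 6 transposed-convolution levels mirror the LSFE; the
  corresponding skip map is spliced in before each level's convolutions, the
  decoded pseudo-sequence is linearly interpolated to the exact text length,
  and a per-position head over [main input A || condition Y || decoded
  features] produces the 40-tag label score sequence.

The main input A is the fused sentence+paragraph attention data (replacing
the white noise of a plain conditional GAN); ``main_input="noise"`` restores
the white-noise baseline, and ``condition="L"`` swaps the generator condition
from Y to the gold label sequence (zeros at inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import ModelConfig
from .encoders import AGFE, CGFE, SGFE, fuse_attention
from .nn import Conv1d, ConvTranspose1d, Dropout, Embedding, LayerNorm, Linear, Module

__all__ = ["Batch", "LSFE", "FALGDecoder", "Generator", "interp_matrix"]


@dataclass
class Batch:
    """One minibatch of sentences with their paragraph/chapter context."""

    sent_ids: np.ndarray  # (B, T) int
    sent_mask: np.ndarray  # (B, T) bool
    para_ids: np.ndarray  # (P, Tp) int
    para_mask: np.ndarray  # (P, Tp) bool
    sent_para: list  # per sentence: (paragraph slot, char offset, length)
    chapter_ids: list  # unique chapter id arrays
    sent_chapter: list  # per sentence: chapter slot
    gold_ids: np.ndarray  # (B, T) int tag ids (0 at padding)
    gold_onehot: np.ndarray  # (B, T, n_tags)

    @property
    def n_sentences(self) -> int:
        return self.sent_ids.shape[0]

    @property
    def max_len(self) -> int:
        return self.sent_ids.shape[1]


def _channel_ln(x: Tensor, ln: LayerNorm) -> Tensor:
    """Layer norm over the channel axis of a (B, C, T) map."""
    return ln(x.transpose(0, 2, 1)).transpose(0, 2, 1)


class LSFE(Module):
    """6-level downsampling encoder over the seed pseudo-sequence."""

    def __init__(self, seed_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.proj = Linear(seed_dim, cfg.seed_len * cfg.seed_channels, rng)
        self.seed_len = cfg.seed_len
        self.seed_channels = cfg.seed_channels
        chans = [cfg.seed_channels, *cfg.lsfe_channels]
        self.convs = [
            Conv1d(chans[i], chans[i + 1], 4, rng, stride=2, padding=1) for i in range(6)
        ]
        self.lns = [LayerNorm(c) for c in cfg.lsfe_channels]

    def __call__(self, seed: Tensor) -> tuple[list[Tensor], Tensor]:
        """seed: (1, seed_dim) -> (skips level 1..6, bottom = level-6 map)."""
        x = self.proj(seed).reshape(1, self.seed_channels, self.seed_len)
        skips: list[Tensor] = []
        for i, (conv, ln) in enumerate(zip(self.convs, self.lns)):
            x = _channel_ln(conv(x), ln)
            x = x.tanh() if i == 5 else x.relu()
            skips.append(x)
        return skips, skips[-1]


class FALGDecoder(Module):
    """6-level upsampling decoder with skip splicing and a per-position head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        enc = list(cfg.lsfe_channels)  # encoder levels 1..6
        dec = list(cfg.decoder_channels)
        self.blocks = []
        prev = enc[-1]  # bottom
        for lvl in range(6):
            skip_ch = enc[5 - lvl]  # decoder level l takes encoder level 7-l
            block = _DecoderBlock(prev + skip_ch, dec[lvl], lvl, rng)
            self.blocks.append(block)
            prev = dec[lvl]
        self.out_channels = dec[-1]

    def __call__(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        x = bottom
        for lvl, block in enumerate(self.blocks):
            skip = skips[5 - lvl]
            if skip.shape[-1] != x.shape[-1]:
                raise ValueError(
                    f"skip length {skip.shape[-1]} != decoder input {x.shape[-1]}"
                )
            x = block(concat([x, skip], axis=1))
        return x  # (1, C, seed_len)


class _DecoderBlock(Module):
    """Level 1: convT+LN+ReLU.  Levels 2-5: convT+conv with two LN/ReLU.
    Level 6: convT+conv, a single LN, ReLU then tanh."""

    def __init__(self, c_in: int, c_out: int, level: int, rng: np.random.Generator):
        self.level = level
        self.convt = ConvTranspose1d(c_in, c_out, 4, rng, stride=2, padding=1)
        self.ln1 = LayerNorm(c_out)
        if level >= 1:
            self.conv = Conv1d(c_out, c_out, 3, rng, padding=1)
            self.ln2 = LayerNorm(c_out) if level < 5 else None

    def __call__(self, x: Tensor) -> Tensor:
        x = _channel_ln(self.convt(x), self.ln1).relu()
        if self.level == 0:
            return x
        x = self.conv(x)
        if self.level < 5:
            return _channel_ln(x, self.ln2).relu()
        return x.tanh()  # level 6: single LN, final activation tanh


def interp_matrix(src: int, dst: int) -> np.ndarray:
    """Linear interpolation matrix M (src, dst): y = x @ M resamples the last
    axis of a (…, src) signal to length dst."""
    m = np.zeros((src, dst))
    if dst == 1:
        m[:, 0] = 1.0 / src  # average
        return m
    pos = np.linspace(0, src - 1, dst)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    w = pos - lo
    for t in range(dst):
        m[lo[t], t] += 1.0 - w[t]
        m[hi[t], t] += w[t]
    return m


class Generator(Module):
    """MTFE + C-U-NET: multigranularity encoders feeding a conditioned U-Net
    that emits a per-position label score sequence."""

    def __init__(
        self,
        vocab_size: int,
        n_tags: int,
        seed_dim: int,
        cfg: ModelConfig,
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        mcfg = cfg.mtfe()
        gran = set(cfg.granularities)
        shared = Embedding(vocab_size, cfg.d_model, rng) if cfg.share_embeddings else None
        if "char" in gran:
            self.cgfe = CGFE(vocab_size, mcfg, rng, emb=shared)
        if "sentence" in gran:
            self.sgfe = SGFE(vocab_size, mcfg, rng, emb=shared)
        if "paragraph" in gran:
            self.pgfe = SGFE(vocab_size, mcfg, rng, emb=shared)
        if "chapter" in gran:
            self.agfe = AGFE(vocab_size, mcfg, rng, emb=shared)
        if "sentence" in gran and "paragraph" in gran:
            self.proj_s = Linear(cfg.d_model, cfg.d_model, rng, bias=False)
            self.proj_p = Linear(cfg.d_model, cfg.d_model, rng, bias=False)
        self.lsfe = LSFE(seed_dim, cfg, rng)
        self.falg = FALGDecoder(cfg, rng)

        self.d_attention = cfg.d_model * sum(
            1 for g in ("sentence", "paragraph") if g in gran
        )
        cond_dim = 0
        if "char" in gran:
            cond_dim += cfg.d_model
        if {"sentence", "paragraph"} & gran:
            cond_dim += cfg.d_model
        if "chapter" in gran:
            cond_dim += cfg.article_dim
        cond_dim += cfg.lsfe_channels[-1]  # projected U-Net bottom
        self.mgffl_proj = Linear(cond_dim, cfg.d_condition, rng)
        if cfg.condition == "L":
            self.cond_l_proj = Linear(n_tags, cfg.d_condition, rng)
        head_in = self.d_attention + cfg.d_condition + self.falg.out_channels
        self.head1 = Linear(head_in, cfg.d_head, rng)
        self.head2 = Linear(cfg.d_head, n_tags, rng)
        self.head_drop = Dropout(cfg.dropout, rng)
        self.n_tags = n_tags
        self._noise_rng = np.random.default_rng(rng.integers(2**31))
        self._training = True

    # -- mode switches ---------------------------------------------------------
    def set_training(self, training: bool) -> None:
        self._training = training
        for name in ("cgfe", "sgfe", "pgfe", "agfe"):
            enc = getattr(self, name, None)
            if enc is not None:
                enc.set_training(training)
        self.head_drop.training = training

    # -- sub-computations ------------------------------------------------------
    def _gather_paragraph(self, par_out: Tensor, batch: Batch) -> Tensor:
        """Re-split paragraph-level per-character features to sentences."""
        b, t = batch.sent_ids.shape
        d = par_out.shape[-1]
        rows = []
        for p_slot, off, length in batch.sent_para:
            piece = par_out[p_slot, off : off + length, :]
            if length < t:
                piece = concat([piece, Tensor(np.zeros((t - length, d)))], axis=0)
            rows.append(piece.reshape(1, t, d))
        return concat(rows, axis=0)

    def _chapter_features(self, batch: Batch) -> Tensor:
        uniq = [self.agfe(ids) for ids in batch.chapter_ids]
        rows = [uniq[c].reshape(1, -1) for c in batch.sent_chapter]
        return concat(rows, axis=0)  # (B, article_dim)

    def mgffl_fuse(
        self,
        h_c: Tensor | None,
        h_s: Tensor | None,
        h_p: Tensor | None,
        h_a: Tensor | None,
        bottom: Tensor,
        batch: Batch,
    ) -> Tensor:
        """Per-position splice of multigranularity features with the U-Net
        bottom; sentence+paragraph features combine by contraposition
        addition after projection."""
        b, t = batch.sent_ids.shape
        blocks: list[Tensor] = []
        if h_c is not None:
            blocks.append(h_c)
        if h_s is not None and h_p is not None:
            blocks.append(self.proj_s(h_s) + self.proj_p(h_p))
        elif h_s is not None:
            blocks.append(h_s)
        elif h_p is not None:
            blocks.append(h_p)
        if h_a is not None:
            da = h_a.shape[-1]
            blocks.append(h_a.reshape(b, 1, da) + Tensor(np.zeros((b, t, da))))
        cb = bottom.shape[1]
        blocks.append(bottom.reshape(1, 1, cb) + Tensor(np.zeros((b, t, cb))))
        y = self.mgffl_proj(concat(blocks, axis=-1))
        return y * Tensor(batch.sent_mask[:, :, None].astype(float))

    def falg_decode(self, a: Tensor, y: Tensor, skips: list[Tensor], bottom: Tensor,
                    mask: np.ndarray) -> Tensor:
        """Decode to a per-position label score sequence of the text length."""
        u = self.falg(bottom, skips)  # (1, C, seed_len)
        t = a.shape[1]
        u_t = (u @ Tensor(interp_matrix(u.shape[-1], t))).transpose(0, 2, 1)  # (1,T,C)
        b = a.shape[0]
        u_bt = u_t + Tensor(np.zeros((b, t, 1)))  # broadcast over the batch
        z = concat([a, y, u_bt], axis=-1)
        scores = self.head2(self.head_drop(self.head1(z).relu()))
        return scores * Tensor(mask[:, :, None].astype(float))

    # -- full forward ----------------------------------------------------------
    def __call__(self, batch: Batch, seed_vec: Tensor) -> Tensor:
        gran = set(self.cfg.granularities)
        mask = batch.sent_mask
        h_c = self.cgfe(batch.sent_ids, mask) if "char" in gran else None
        a_s = h_s = a_p = h_p = None
        if "sentence" in gran:
            a_s, h_s = self.sgfe(batch.sent_ids, mask)
        if "paragraph" in gran:
            a_par, h_par = self.pgfe(batch.para_ids, batch.para_mask)
            a_p = self._gather_paragraph(a_par, batch)
            h_p = self._gather_paragraph(h_par, batch)
        h_a = self._chapter_features(batch) if "chapter" in gran else None

        attn_streams = [x for x in (a_s, a_p) if x is not None]
        if self.cfg.main_input == "noise":
            a = Tensor(
                self._noise_rng.normal(
                    size=(batch.n_sentences, batch.max_len, self.d_attention)
                )
                * mask[:, :, None]
            )
        elif len(attn_streams) == 2:
            a = fuse_attention(attn_streams[0], attn_streams[1])
        else:
            a = attn_streams[0]

        skips, bottom = self.lsfe(seed_vec)
        if self.cfg.condition == "L":
            # gold labels are unavailable at inference: zero condition
            cond_in = batch.gold_onehot if self._training else batch.gold_onehot * 0.0
            y = self.cond_l_proj(Tensor(cond_in))
        else:
            y = self.mgffl_fuse(h_c, h_s, h_p, h_a, bottom, batch)
        return self.falg_decode(a, y, skips, bottom, mask)
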