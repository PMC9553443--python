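"""Adversarial and supervised losses.

The adversarial game is the standard conditional min-max: the discriminator
maximises E[log D(real|L)] + E[log(1 - D(fake|Y))]; the generator minimises
the fake term.  The generator's total loss combines per-position
cross-entropy supervision with the adversarial term as CE + lambda * adv —
the standard realisation of coupling a cross-entropy objective with the
min-max value.  Scores are epsilon-clamped before logs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["adversarial_loss", "cross_entropy", "total_generator_loss", "EPS"]

EPS = 1e-7


def adversarial_loss(d_real: Tensor, d_fake: Tensor) -> tuple[Tensor, Tensor]:
    """(discriminator loss, generator-side adversarial loss).

    loss_D = -[E log D(real) + E log(1 - D(fake))];
    loss_G_adv = E log(1 - D(fake))  (the generator minimises it).
    At the equilibrium d_real = d_fake = 1/2, loss_D = 2 log 2.
    """
    dr = d_real.clip(EPS, 1.0 - EPS)
    df = d_fake.clip(EPS, 1.0 - EPS)
    loss_d = -(dr.log().mean() + (1.0 - df).log().mean())
    loss_g_adv = (1.0 - df).log().mean()
    return loss_d, loss_g_adv


def cross_entropy(
    scores: Tensor,
    gold_onehot: np.ndarray,
    mask: np.ndarray,
    reduction: str = "sum",
) -> Tensor:
    """Per-position softmax cross-entropy against gold tags.

    scores: (B, T, n_tags); gold_onehot: same shape; mask: (B, T) boolean.
    """
    m = scores.max(axis=-1, keepdims=True)
    z = scores - m
    logp = z - z.exp().sum(axis=-1, keepdims=True).log()
    nll = -(logp * Tensor(gold_onehot)).sum(axis=-1)  # (B, T)
    nll = nll * Tensor(np.asarray(mask, float))
    if reduction == "sum":
        return nll.sum()
    if reduction == "mean":
        return nll.sum() * (1.0 / float(np.asarray(mask).sum()))
    raise ValueError(f"unknown reduction {reduction!r}")


def total_generator_loss(
    scores: Tensor,
    gold_onehot: np.ndarray,
    mask: np.ndarray,
    loss_g_adv: Tensor | float = 0.0,
    lam: float = 1.0,
    reduction: str = "sum",
) -> Tensor:
    """CE + lambda * adversarial term."""
    ce = cross_entropy(scores, gold_onehot, mask, reduction)
    if lam == 0.0:
        return ce
    adv = loss_g_adv if isinstance(loss_g_adv, Tensor) else Tensor(loss_g_adv)
    return ce + lam * adv
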