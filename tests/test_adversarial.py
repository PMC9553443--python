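"""Discriminator behaviour, loss closed forms, and training-loop sanity."""

import numpy as np
import pytest

from mtcgan.autodiff import Tensor
from mtcgan.config import ModelConfig
from mtcgan.discriminator import Discriminator
from mtcgan.losses import adversarial_loss, cross_entropy, total_generator_loss
from mtcgan.model import MTCGAN, TrainingDivergence
from mtcgan.nn import Adam
from mtcgan.synthetic import easy_config, generate

from test_unet import tiny_model_cfg


# -- discriminator ----------------------------------------------------------------


def test_discriminator_score_range_and_determinism(rng):
    disc = Discriminator(n_tags=40, cfg=tiny_model_cfg(), rng=rng)
    x = Tensor(np.random.default_rng(0).normal(size=(3, 7, 40)))
    cond = Tensor(np.random.default_rng(1).normal(size=(3, 7, 40)))
    mask = np.ones((3, 7), bool)
    s1 = disc(x, cond, mask).data
    s2 = disc(x, cond, mask).data
    assert s1.shape == (3,)
    assert np.all((s1 > 0) & (s1 < 1))
    np.testing.assert_array_equal(s1, s2)
    with pytest.raises(ValueError):
        disc(x, Tensor(np.zeros((3, 6, 40))), mask)


def test_discriminator_learns_constant_real_vs_fake(rng):
    """After a short training run the discriminator separates a constant
    'real' pattern from a constant 'fake' one by a clear margin."""
    disc = Discriminator(n_tags=8, cfg=tiny_model_cfg(), rng=rng)
    opt = Adam(disc.parameters(), lr=5e-3)
    mask = np.ones((4, 6), bool)
    real = np.zeros((4, 6, 8))
    real[..., 1] = 1.0  # one-hot 'O'-like pattern
    fake = np.full((4, 6, 8), 1.0 / 8)  # uniform scores
    cond = Tensor(real)
    for _ in range(50):
        d_real = disc(Tensor(real), cond, mask)
        d_fake = disc(Tensor(fake), cond, mask)
        loss, _ = adversarial_loss(d_real, d_fake)
        disc.zero_grad()
        loss.backward()
        opt.step()
    gap = float(disc(Tensor(real), cond, mask).data.mean()
                - disc(Tensor(fake), cond, mask).data.mean())
    assert gap > 0.2


# -- losses ------------------------------------------------------------------------


def test_adversarial_loss_equilibrium_closed_form():
    half = Tensor(np.full(4, 0.5))
    loss_d, loss_g = adversarial_loss(half, half)
    assert abs(loss_d.item() - 2 * np.log(2)) < 1e-6
    assert abs(loss_g.item() - np.log(0.5)) < 1e-6


def test_adversarial_loss_perfect_discriminator_clamped():
    ones = Tensor(np.ones(3))
    zeros = Tensor(np.zeros(3))
    loss_d, _ = adversarial_loss(ones, zeros)
    assert 0 <= loss_d.item() < 1e-5  # -> 0 under epsilon clamping


def test_adversarial_loss_gradient_signs():
    """Finite differences: raising d_fake raises loss_D (and lowers the
    generator-side term)."""
    d_real = Tensor(np.array([0.7]))
    eps = 1e-5
    for base in (0.3, 0.5, 0.8):
        lo = adversarial_loss(d_real, Tensor(np.array([base - eps])))[0].item()
        hi = adversarial_loss(d_real, Tensor(np.array([base + eps])))[0].item()
        assert hi > lo
        g_lo = adversarial_loss(d_real, Tensor(np.array([base - eps])))[1].item()
        g_hi = adversarial_loss(d_real, Tensor(np.array([base + eps])))[1].item()
        assert g_hi < g_lo


def test_cross_entropy_uniform_scores_closed_form():
    """Two positions of uniform scores over 40 tags cost 2 log 40 in total."""
    scores = Tensor(np.zeros((1, 2, 40)))
    gold = np.zeros((1, 2, 40))
    gold[0, 0, 3] = 1.0
    gold[0, 1, 17] = 1.0
    mask = np.ones((1, 2), bool)
    ce = cross_entropy(scores, gold, mask, reduction="sum")
    assert abs(ce.item() - 2 * np.log(40)) < 1e-9


def test_cross_entropy_saturated_gold_scores_vanish():
    scores = Tensor(np.zeros((1, 1, 5)))
    scores.data[0, 0, 2] = 50.0  # near-saturated correct tag
    gold = np.zeros((1, 1, 5))
    gold[0, 0, 2] = 1.0
    ce = cross_entropy(scores, gold, np.ones((1, 1), bool))
    assert ce.item() < 1e-12


def test_total_loss_lambda_zero_is_supervised():
    scores = Tensor(np.zeros((1, 2, 40)))
    gold = np.zeros((1, 2, 40))
    gold[0, 0, 0] = gold[0, 1, 1] = 1.0
    mask = np.ones((1, 2), bool)
    total = total_generator_loss(scores, gold, mask, Tensor(123.0), lam=0.0)
    ce = cross_entropy(scores, gold, mask)
    assert total.item() == ce.item()
    with_adv = total_generator_loss(scores, gold, mask, Tensor(2.0), lam=0.5)
    assert abs(with_adv.item() - (ce.item() + 1.0)) < 1e-12


# -- training loop -----------------------------------------------------------------


@pytest.fixture(scope="module")
def ten_sentence_corpus(catalog):
    cfg = easy_config(n_sentences=20, rng_seed=6)
    docs, _ = generate(cfg, catalog)
    # keep exactly the first 10 sentences (hierarchy trimmed accordingly)
    chapters = docs[0].chapters[:1]
    chapters[0] = chapters[0][:3]
    chapters[0][2] = chapters[0][2][:2]
    from mtcgan import AnnotatedDocument

    doc = AnnotatedDocument(chapters=chapters, doc_type=docs[0].doc_type)
    assert doc.n_sentences() == 10
    return [doc]


def test_one_epoch_smoke_all_losses_finite(ten_sentence_corpus):
    cfg = tiny_model_cfg(epochs=1, crf_iters=5)
    res = MTCGAN(ten_sentence_corpus, config=cfg).fit(rng_seed=0)
    row = res.history.iloc[0]
    assert np.isfinite(row["loss_D"]) and np.isfinite(row["loss_G"])


def test_supervised_ce_monotone_on_memorizable_corpus(ten_sentence_corpus):
    """lambda=0, frozen discriminator: training cross-entropy is monotonically
    non-increasing across epochs on a 10-sentence corpus."""
    cfg = tiny_model_cfg(
        epochs=5, lambda_adv=0.0, freeze_discriminator=True, lr=3e-3, crf_iters=5
    )
    res = MTCGAN(ten_sentence_corpus, config=cfg).fit(rng_seed=0)
    ce = res.history["loss_G"].to_numpy()
    assert np.all(np.diff(ce) <= 1e-9), f"CE not monotone: {ce}"


def test_divergence_guard_aborts_on_non_finite_loss():
    with pytest.raises(TrainingDivergence, match="generator"):
        MTCGAN._guard(Tensor(np.nan), "generator")
    with pytest.raises(TrainingDivergence, match="discriminator"):
        MTCGAN._guard(Tensor(np.inf), "discriminator")
    MTCGAN._guard(Tensor(1.0), "generator")  # finite passes
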