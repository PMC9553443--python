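"""Conditioned U-Net generator: seed encoder shapes, skip wiring, decoder
length contract, fusion layer block structure, gradient liveness."""

import numpy as np
import pytest

from mtcgan.autodiff import Tensor
from mtcgan.config import ModelConfig, compact_profile, desk_profile
from mtcgan.generator import FALGDecoder, Generator, LSFE, interp_matrix
from mtcgan.model import MTCGAN, _make_batch, _prepare
from mtcgan.synthetic import easy_config, generate


def tiny_model_cfg(**kw):
    base = dict(
        d_model=16,
        gru_hidden=8,
        article_dim=8,
        seed_d_emb=4,
        lsfe_channels=(4, 4, 8, 8, 8, 8),
        decoder_channels=(8, 8, 8, 8, 8, 8),
        d_condition=12,
        d_head=16,
        disc_channels=8,
        dropout=0.0,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def prepared(catalog):
    docs, _ = generate(easy_config(n_sentences=20, rng_seed=5), catalog)
    cfg = tiny_model_cfg()
    model = MTCGAN(docs, config=cfg)
    return model


def make_batch_of(model, n_paras=1):
    batch, _ = _make_batch(
        model.train_prep, list(range(n_paras)), len(model.tags)
    )
    return batch


# -- LSFE -----------------------------------------------------------------------


def test_lsfe_halves_length_per_level(rng):
    cfg = tiny_model_cfg(seed_len=128)
    lsfe = LSFE(seed_dim=76, cfg=cfg, rng=rng)
    skips, bottom = lsfe(Tensor(rng.normal(size=(1, 76))))
    assert [s.shape[-1] for s in skips] == [64, 32, 16, 8, 4, 2]
    assert bottom.shape[-1] == 2
    # layer-6 output passes through tanh
    assert np.all(np.abs(bottom.data) < 1.0)


def test_lsfe_deterministic_forward(rng):
    cfg = tiny_model_cfg()
    lsfe = LSFE(seed_dim=76, cfg=cfg, rng=rng)
    seed = Tensor(np.random.default_rng(1).normal(size=(1, 76)))
    a = lsfe(seed)[1].data
    b = lsfe(seed)[1].data
    np.testing.assert_array_equal(a, b)


def test_seed_len_not_multiple_of_64_rejected():
    with pytest.raises(ValueError, match="seed_len"):
        tiny_model_cfg(seed_len=100)


# -- FALG decoder ------------------------------------------------------------------


def test_falg_skip_shape_mismatch_raises(rng):
    cfg = tiny_model_cfg()
    lsfe = LSFE(seed_dim=76, cfg=cfg, rng=rng)
    falg = FALGDecoder(cfg, rng)
    skips, bottom = lsfe(Tensor(rng.normal(size=(1, 76))))
    broken = list(skips)
    broken[0] = skips[1]  # wrong length at the last decoder level
    with pytest.raises(ValueError, match="skip"):
        falg(bottom, broken)


def test_interp_matrix_endpoints_and_rows():
    m = interp_matrix(4, 7)
    np.testing.assert_allclose(m.sum(axis=0), 1.0)  # each output is a convex mix
    np.testing.assert_allclose((np.arange(4.0) @ m)[0], 0.0)
    np.testing.assert_allclose((np.arange(4.0) @ m)[-1], 3.0)
    m1 = interp_matrix(4, 1)
    np.testing.assert_allclose(m1.sum(axis=0), 1.0)


# -- generator end-to-end ------------------------------------------------------------


@pytest.mark.parametrize("n_sent", [5, 17])
def test_generator_output_matches_text_length(catalog, n_sent):
    cfg = easy_config(n_sentences=20, rng_seed=5)
    docs, _ = generate(cfg, catalog)
    model = MTCGAN(docs, config=tiny_model_cfg())
    rng = np.random.default_rng(0)
    gen = Generator(model.vocab.size, len(model.tags), model.seed.data.size,
                    model.config, rng)
    gen.set_training(False)
    batch = make_batch_of(model, n_paras=2)
    # exercise odd lengths via the batch's natural ragged sentences
    scores = gen(batch, Tensor(model.seed.data[None]))
    assert scores.shape == (batch.n_sentences, batch.max_len, 40)
    # masked positions carry zero scores
    assert np.all(scores.data[~batch.sent_mask] == 0.0)


def test_generator_skips_are_live(prepared):
    """Zeroing a skip connection changes the output."""
    model = prepared
    rng = np.random.default_rng(0)
    gen = Generator(model.vocab.size, len(model.tags), model.seed.data.size,
                    model.config, rng)
    gen.set_training(False)
    batch = make_batch_of(model)
    seed_vec = Tensor(model.seed.data[None])
    base = gen(batch, seed_vec).data.copy()
    # zero the weights feeding the level-1 skip splice contribution:
    # ablate by zeroing the stored LSFE level-5 conv output path instead —
    # easiest faithful perturbation: zero the conv weights of LSFE level 5
    w = gen.lsfe.convs[4].weight
    orig = w.data.copy()
    w.data[:] = 0.0
    perturbed = gen(batch, seed_vec).data
    w.data[:] = orig
    assert not np.allclose(base, perturbed)


def test_generator_white_noise_mode(prepared):
    model = prepared
    cfg = model.config.with_(main_input="noise")
    rng = np.random.default_rng(0)
    gen = Generator(model.vocab.size, len(model.tags), model.seed.data.size, cfg, rng)
    gen.set_training(False)
    batch = make_batch_of(model)
    seed_vec = Tensor(model.seed.data[None])
    a = gen(batch, seed_vec).data
    b = gen(batch, seed_vec).data
    assert a.shape == b.shape
    assert not np.allclose(a, b)  # fresh noise per forward


def test_gradient_reaches_every_parameter_group(prepared):
    """No dead submodule: a loss on the output sends gradient to every
    parameter tensor of the generator."""
    model = prepared
    rng = np.random.default_rng(0)
    gen = Generator(model.vocab.size, len(model.tags), model.seed.data.size,
                    model.config, rng)
    gen.set_training(True)
    batch = make_batch_of(model, n_paras=2)
    scores = gen(batch, Tensor(model.seed.data[None]))
    (scores * scores).sum().backward()
    dead = [
        name
        for name, p in gen.named_parameters()
        if p.grad is None or not np.any(p.grad)
    ]
    # embedding rows for unused characters legitimately receive zero gradient,
    # but whole-tensor zeros indicate a dead module
    assert dead == [], f"dead parameter groups: {dead}"


def test_condition_swap_changes_scores(prepared):
    model = prepared
    batch = make_batch_of(model)
    seed_vec = Tensor(model.seed.data[None])
    outs = {}
    for cond in ("Y", "L"):
        rng = np.random.default_rng(0)
        gen = Generator(
            model.vocab.size, len(model.tags), model.seed.data.size,
            model.config.with_(condition=cond), rng,
        )
        gen.set_training(True)
        outs[cond] = gen(batch, seed_vec).data
    assert not np.allclose(outs["Y"], outs["L"])


def test_granularity_subsets_build_and_run(prepared):
    model = prepared
    batch = make_batch_of(model)
    seed_vec = Tensor(model.seed.data[None])
    for gran in (
        ("sentence", "paragraph"),
        ("char", "sentence"),
        ("char", "paragraph"),
        ("sentence", "paragraph", "chapter"),
    ):
        gen = Generator(
            model.vocab.size, len(model.tags), model.seed.data.size,
            model.config.with_(granularities=gran), np.random.default_rng(0),
        )
        gen.set_training(False)
        scores = gen(batch, seed_vec)
        assert scores.shape == (batch.n_sentences, batch.max_len, 40)
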