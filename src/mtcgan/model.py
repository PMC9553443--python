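"""Model and results objects for conditional-GAN sequence labelling.

:class:`MTCGAN` is built from annotated corpora plus a :class:`~mtcgan.config.
ModelConfig`; :meth:`MTCGAN.fit` runs the alternating adversarial training
(k discriminator steps, then one generator step, per minibatch; Adam for both
nets with per-epoch multiplicative learning-rate decay), fits a linear-chain
CRF post hoc on the trained generator's label scores, and returns a
:class:`MTCGANResults` carrying the parameters, the per-epoch history and the
development-set metrics.

A minibatch is a group of whole paragraphs: each sentence travels with its
paragraph (for the paragraph-granularity encoder, whose attention spans
sentence boundaries) and its chapter (for the chapter-granularity encoder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses
from .autodiff import Tensor, masked_softmax, no_grad
from .catalog import EntityType, EntityTypeCatalog, default_catalog
from .config import ModelConfig, desk_profile
from .corpus import AnnotatedDocument, Vocabulary, build_vocab, encode
from .crf import CrfParams, crf_fit, viterbi_decode
from .discriminator import Discriminator
from .generator import Batch, Generator
from .metrics import evaluate
from .seed import SeedVector, build_seed

__all__ = ["MTCGAN", "MTCGANResults", "TrainingDivergence", "train"]


class TrainingDivergence(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class _Prepared:
    """Corpus flattened for batching."""

    sent_chars: list  # per sentence: list of characters
    sent_tags: list  # per sentence: list of tag strings
    sent_tag_ids: list  # per sentence: np int array
    sent_para: list  # per sentence: (paragraph index, char offset)
    sent_chapter: list  # per sentence: chapter index
    para_ids: list  # per paragraph: np int id array (sentences concatenated)
    chapter_ids: list  # per chapter: np int id array
    para_sentences: list  # per paragraph: list of sentence indices

    @property
    def n_sentences(self) -> int:
        return len(self.sent_chars)


def _prepare(
    docs: list[AnnotatedDocument], vocab: Vocabulary, tag_index: dict[str, int]
) -> _Prepared:
    prep = _Prepared([], [], [], [], [], [], [], [])
    for doc in docs:
        for paragraphs in doc.chapters:
            chap_idx = len(prep.chapter_ids)
            chap_ids: list[int] = []
            for sentences in paragraphs:
                para_idx = len(prep.para_ids)
                para_ids: list[int] = []
                sent_slots = []
                offset = 0
                for sent in sentences:
                    ids, _ = encode(sent, vocab)
                    chars = [c for c, _ in sent]
                    tags = [t for _, t in sent]
                    sent_slots.append(len(prep.sent_chars))
                    prep.sent_chars.append(chars)
                    prep.sent_tags.append(tags)
                    prep.sent_tag_ids.append(
                        np.array([tag_index[t] for t in tags], dtype=np.intp)
                    )
                    prep.sent_para.append((para_idx, offset))
                    prep.sent_chapter.append(chap_idx)
                    para_ids.extend(ids.tolist())
                    chap_ids.extend(ids.tolist())
                    offset += len(ids)
                prep.para_ids.append(np.array(para_ids, dtype=np.intp))
                prep.para_sentences.append(sent_slots)
            prep.chapter_ids.append(np.array(chap_ids, dtype=np.intp))
    return prep


def _make_batch(prep: _Prepared, para_slots: list[int], n_tags: int) -> Batch:
    sent_idx = [s for p in para_slots for s in prep.para_sentences[p]]
    b = len(sent_idx)
    t = max(len(prep.sent_chars[s]) for s in sent_idx)
    sent_ids = np.zeros((b, t), dtype=np.intp)
    sent_mask = np.zeros((b, t), dtype=bool)
    gold_ids = np.zeros((b, t), dtype=np.intp)
    para_map = {p: i for i, p in enumerate(para_slots)}
    chap_slots: list[int] = []
    sent_para = []
    sent_chapter = []
    for row, s in enumerate(sent_idx):
        n = len(prep.sent_chars[s])
        p_idx0, off0 = prep.sent_para[s]
        sent_ids[row, :n] = prep.para_ids[p_idx0][off0 : off0 + n]
        sent_mask[row, :n] = True
        gold_ids[row, :n] = prep.sent_tag_ids[s]
        sent_para.append((para_map[p_idx0], off0, n))
        c_idx = prep.sent_chapter[s]
        if c_idx not in chap_slots:
            chap_slots.append(c_idx)
        sent_chapter.append(chap_slots.index(c_idx))
    tp = max(len(prep.para_ids[p]) for p in para_slots)
    para_ids = np.zeros((len(para_slots), tp), dtype=np.intp)
    para_mask = np.zeros((len(para_slots), tp), dtype=bool)
    for i, p in enumerate(para_slots):
        n = len(prep.para_ids[p])
        para_ids[i, :n] = prep.para_ids[p]
        para_mask[i, :n] = True
    onehot = np.zeros((b, t, n_tags))
    rows = np.repeat(np.arange(b), t)
    cols = np.tile(np.arange(t), b)
    onehot[rows, cols, gold_ids.reshape(-1)] = 1.0
    onehot *= sent_mask[:, :, None]
    return Batch(
        sent_ids=sent_ids,
        sent_mask=sent_mask,
        para_ids=para_ids,
        para_mask=para_mask,
        sent_para=sent_para,
        chapter_ids=[prep.chapter_ids[c] for c in chap_slots],
        sent_chapter=sent_chapter,
        gold_ids=gold_ids,
        gold_onehot=onehot,
    ), sent_idx


def _paragraph_batches(
    prep: _Prepared, batch_size: int, order: np.ndarray
) -> list[list[int]]:
    batches: list[list[int]] = []
    cur: list[int] = []
    n = 0
    for p in order:
        cur.append(int(p))
        n += len(prep.para_sentences[int(p)])
        if n >= batch_size:
            batches.append(cur)
            cur, n = [], 0
    if cur:
        batches.append(cur)
    return batches


class MTCGAN:
    """Conditional-GAN named entity recogniser for small annotated corpora.

    Parameters
    ----------
    train_docs, dev_docs : annotated document collections (dev optional).
    catalog : entity-type catalog; defaults to the standard 19 types.
    config : :class:`ModelConfig`; defaults to the desk profile.
    """

    def __init__(
        self,
        train_docs: list[AnnotatedDocument],
        dev_docs: list[AnnotatedDocument] | None = None,
        catalog: EntityTypeCatalog | None = None,
        config: ModelConfig | None = None,
    ):
        if not train_docs or all(d.n_sentences() == 0 for d in train_docs):
            raise ValueError("training corpus is empty")
        self.catalog = catalog or default_catalog()
        self.config = config or desk_profile()
        for doc in train_docs:
            doc.validate(self.catalog)
        self.tags = self.catalog.tag_list()
        self.tag_index = {t: i for i, t in enumerate(self.tags)}
        self.vocab = build_vocab(train_docs, self.config.min_count)
        self.train_prep = _prepare(train_docs, self.vocab, self.tag_index)
        self.dev_prep = (
            _prepare(dev_docs, self.vocab, self.tag_index) if dev_docs else None
        )
        # the seed is computed on the training split only (no leakage)
        self.seed: SeedVector = build_seed(
            self.catalog,
            train_docs,
            d_emb=self.config.seed_d_emb,
            rng_seed=self.config.seed_rng,
            corpus_type=train_docs[0].doc_type,
            mode=self.config.seed_mode,
        )

    # -- training ---------------------------------------------------------------
    def fit(self, rng_seed: int = 0, verbose: bool = False) -> "MTCGANResults":
        cfg = self.config
        rng = np.random.default_rng(rng_seed)
        gen = Generator(
            self.vocab.size, len(self.tags), self.seed.data.size, cfg, rng
        )
        disc = Discriminator(len(self.tags), cfg, rng)
        from .nn import Adam

        opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.adam_betas,
                     eps=cfg.adam_eps, clip_norm=cfg.clip_norm)
        opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.adam_betas,
                     eps=cfg.adam_eps, clip_norm=cfg.clip_norm)
        seed_vec = Tensor(self.seed.data[None, :])
        history: list[dict] = []
        for epoch in range(1, cfg.epochs + 1):
            gen.set_training(True)
            order = rng.permutation(len(self.train_prep.para_ids))
            batches = _paragraph_batches(self.train_prep, cfg.batch_size, order)
            ep_loss_d, ep_loss_g, n_steps = 0.0, 0.0, 0
            for para_slots in batches:
                batch, _ = _make_batch(self.train_prep, para_slots, len(self.tags))
                real = Tensor(batch.gold_onehot)
                # --- k discriminator steps (generator fixed)
                loss_d = Tensor(0.0)
                for _ in range(0 if cfg.freeze_discriminator else cfg.k_disc):
                    with no_grad():
                        fake_scores = gen(batch, seed_vec)
                        fake_probs = masked_softmax(fake_scores).data
                    d_real = disc(real, real, batch.sent_mask)
                    d_fake = disc(Tensor(fake_probs), real, batch.sent_mask)
                    loss_d, _ = losses.adversarial_loss(d_real, d_fake)
                    self._guard(loss_d, "discriminator")
                    disc.zero_grad()
                    loss_d.backward()
                    opt_d.step()
                # --- one generator step (discriminator fixed)
                scores = gen(batch, seed_vec)
                if cfg.lambda_adv == 0.0:
                    loss_g_adv = Tensor(0.0)
                else:
                    fake_probs_t = masked_softmax(scores)
                    d_fake = disc(fake_probs_t, real, batch.sent_mask)
                    _, loss_g_adv = losses.adversarial_loss(d_fake.detach(), d_fake)
                loss_g = losses.total_generator_loss(
                    scores,
                    batch.gold_onehot,
                    batch.sent_mask,
                    loss_g_adv,
                    lam=cfg.lambda_adv,
                    reduction="mean",
                )
                self._guard(loss_g, "generator")
                gen.zero_grad()
                disc.zero_grad()
                loss_g.backward()
                opt_g.step()
                ep_loss_d += loss_d.item()
                ep_loss_g += loss_g.item()
                n_steps += 1
            opt_g.decay_lr(cfg.lr_decay)
            opt_d.decay_lr(cfg.lr_decay)
            row = {
                "epoch": epoch,
                "loss_D": ep_loss_d / max(n_steps, 1),
                "loss_G": ep_loss_g / max(n_steps, 1),
                "dev_P": np.nan,
                "dev_R": np.nan,
                "dev_F1": np.nan,
            }
            cadence = cfg.eval_dev_every
            if self.dev_prep is not None and cadence and (
                epoch % cadence == 0 or epoch == cfg.epochs
            ):
                m = self._greedy_metrics(gen, seed_vec, self.dev_prep)
                row.update(dev_P=m["P"], dev_R=m["R"], dev_F1=m["F1"])
            history.append(row)
            if verbose:
                print(
                    f"epoch {epoch:3d}  loss_D {row['loss_D']:.4f}  "
                    f"loss_G {row['loss_G']:.4f}  dev_F1 {row['dev_F1']:.2f}"
                )
        # post-hoc CRF on the trained generator's scores
        crf = self._fit_crf(gen, seed_vec)
        results = MTCGANResults(
            model=self,
            gen_state=gen.state_dict(),
            disc_state=disc.state_dict(),
            crf=crf,
            history=pd.DataFrame(history),
            rng_seed=rng_seed,
        )
        if self.dev_prep is not None:
            results.dev_metrics = results._evaluate_prep(self.dev_prep)
        return results

    @staticmethod
    def _guard(loss: Tensor, which: str) -> None:
        if not np.isfinite(loss.data).all():
            raise TrainingDivergence(f"{which} loss became non-finite")

    # -- score extraction ---------------------------------------------------------
    def _all_scores(self, gen: Generator, seed_vec: Tensor, prep: _Prepared):
        """Per-sentence (scores array, gold ids, tags) with dropout off."""
        gen.set_training(False)
        out: list[tuple[np.ndarray, np.ndarray, list[str]]] = []
        slots = list(range(len(prep.para_ids)))
        order = np.arange(len(slots))
        for para_slots in _paragraph_batches(prep, self.config.batch_size, order):
            batch, sent_idx = _make_batch(prep, para_slots, len(self.tags))
            with no_grad():
                scores = gen(batch, seed_vec).data
            for row, s in enumerate(sent_idx):
                n = len(prep.sent_chars[s])
                out.append((scores[row, :n], prep.sent_tag_ids[s], prep.sent_tags[s]))
        gen.set_training(True)
        return out

    def _greedy_metrics(self, gen: Generator, seed_vec: Tensor, prep: _Prepared) -> dict:
        triples = self._all_scores(gen, seed_vec, prep)
        pred = [[self.tags[i] for i in np.argmax(sc, axis=1)] for sc, _, _ in triples]
        gold = [tags for _, _, tags in triples]
        return evaluate(pred, gold)["overall"]

    def _fit_crf(self, gen: Generator, seed_vec: Tensor) -> CrfParams:
        triples = self._all_scores(gen, seed_vec, self.train_prep)
        return crf_fit(
            [sc for sc, _, _ in triples],
            [g for _, g, _ in triples],
            n_tags=len(self.tags),
            tags=self.tags,
            hard_mask=self.config.crf_hard_mask,
            iters=self.config.crf_iters,
        )


@dataclass
class MTCGANResults:
    """Fitted parameters, training history and decoding for a run."""

    model: MTCGAN
    gen_state: dict
    disc_state: dict
    crf: CrfParams
    history: pd.DataFrame
    rng_seed: int
    dev_metrics: dict | None = None

    # -- prediction --------------------------------------------------------------
    def _generator(self) -> tuple[Generator, Tensor]:
        m = self.model
        gen = Generator(
            m.vocab.size, len(m.tags), m.seed.data.size, m.config,
            np.random.default_rng(0),
        )
        gen.load_state_dict(self.gen_state)
        gen.set_training(False)
        return gen, Tensor(m.seed.data[None, :])

    def predict(
        self, docs: list[AnnotatedDocument], decoder: str = "crf"
    ) -> list[list[str]]:
        """Tag sequences for every sentence of `docs` (flattened order)."""
        m = self.model
        prep = _prepare(docs, m.vocab, _PermissiveTagIndex(m.tag_index))
        gen, seed_vec = self._generator()
        triples = m._all_scores(gen, seed_vec, prep)
        out = []
        for sc, _, _ in triples:
            if decoder == "crf":
                ids = viterbi_decode(sc, self.crf)
            elif decoder == "greedy":
                ids = np.argmax(sc, axis=1).tolist()
            else:
                raise ValueError(f"unknown decoder {decoder!r}")
            out.append([m.tags[i] for i in ids])
        return out

    def predict_docs(
        self, docs: list[AnnotatedDocument], decoder: str = "crf"
    ) -> list[AnnotatedDocument]:
        """Copies of `docs` with predicted tags in place of gold tags."""
        flat = iter(self.predict(docs, decoder))
        out = []
        for doc in docs:
            chapters = []
            for paragraphs in doc.chapters:
                new_paras = []
                for sentences in paragraphs:
                    new_sents = []
                    for sent in sentences:
                        tags = next(flat)
                        new_sents.append(
                            [(c, t) for (c, _), t in zip(sent, tags)]
                        )
                    new_paras.append(new_sents)
                chapters.append(new_paras)
            out.append(AnnotatedDocument(chapters=chapters, doc_type=doc.doc_type))
        return out

    def evaluate(self, docs: list[AnnotatedDocument], decoder: str = "crf") -> dict:
        pred = self.predict(docs, decoder)
        gold = [[t for _, t in sent] for doc in docs for sent in doc.sentences()]
        return evaluate(pred, gold)

    def _evaluate_prep(self, prep: _Prepared) -> dict:
        gen, seed_vec = self._generator()
        triples = self.model._all_scores(gen, seed_vec, prep)
        pred = [
            [self.model.tags[i] for i in viterbi_decode(sc, self.crf)]
            for sc, _, _ in triples
        ]
        gold = [tags for _, _, tags in triples]
        return evaluate(pred, gold)

    # -- reporting ---------------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        cfg = m.config
        lines = [
            "Conditional-GAN NER results",
            "=" * 42,
            f"training sentences : {m.train_prep.n_sentences}",
            f"dev sentences      : "
            f"{m.dev_prep.n_sentences if m.dev_prep else 0}",
            f"tag space          : {len(m.tags)} tags "
            f"({m.catalog.n_types} entity types)",
            f"vocabulary         : {m.vocab.size} characters",
            f"granularities      : {', '.join(cfg.granularities)}",
            f"main input         : {cfg.main_input}",
            f"generator condition: {cfg.condition}",
            f"seed mode          : {cfg.seed_mode}",
            f"epochs x batch     : {cfg.epochs} x {cfg.batch_size} "
            f"(k={cfg.k_disc}, lr={cfg.lr:g}, decay={cfg.lr_decay})",
            f"rng seed           : {self.rng_seed}",
            "-" * 42,
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines.append(
                f"final losses       : D={last['loss_D']:.4f} G={last['loss_G']:.4f}"
            )
        if self.dev_metrics is not None:
            o = self.dev_metrics["overall"]
            lines.append(
                f"dev (CRF decode)   : P={o['P']:.2f}% R={o['R']:.2f}% F1={o['F1']:.2f}%"
            )
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": _config_to_dict(self.model.config),
            "tags": self.model.tags,
            "vocab": self.model.vocab.id_to_char,
            "catalog": [
                {"name": t.name, "label": t.label, "doc_types": list(t.doc_types)}
                for t in self.model.catalog.types
            ],
            "rng_seed": self.rng_seed,
            "dev_metrics": self.dev_metrics,
            "history_columns": list(self.history.columns),
        }
        arrays = {f"gen::{k}": v for k, v in self.gen_state.items()}
        arrays.update({f"disc::{k}": v for k, v in self.disc_state.items()})
        arrays.update(
            {
                "crf::transitions": self.crf.transitions,
                "crf::start": self.crf.start,
                "crf::stop": self.crf.stop,
                "seed::data": self.model.seed.data,
                "history::values": self.history.to_numpy(dtype=float),
            }
        )
        np.savez(path, meta=json.dumps(meta), **arrays)

    @staticmethod
    def load(path, train_docs, dev_docs=None) -> "MTCGANResults":
        """Rebuild results around the same corpora (parameters from the file)."""
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = {k: z[k] for k in z.files if k != "meta"}
        cfg = ModelConfig(**_config_from_dict(meta["config"]))
        catalog = EntityTypeCatalog(
            types=[
                EntityType(d["name"], d["label"], tuple(d["doc_types"]))
                for d in meta["catalog"]
            ]
        )
        model = MTCGAN(train_docs, dev_docs, catalog=catalog, config=cfg)
        crf = CrfParams(
            transitions=arrays["crf::transitions"],
            start=arrays["crf::start"],
            stop=arrays["crf::stop"],
            tags=meta["tags"],
            hard_mask=cfg.crf_hard_mask,
        )
        history = pd.DataFrame(
            arrays["history::values"], columns=meta["history_columns"]
        )
        return MTCGANResults(
            model=model,
            gen_state={
                k.split("::", 1)[1]: v for k, v in arrays.items() if k.startswith("gen::")
            },
            disc_state={
                k.split("::", 1)[1]: v
                for k, v in arrays.items()
                if k.startswith("disc::")
            },
            crf=crf,
            history=history,
            rng_seed=meta["rng_seed"],
            dev_metrics=meta["dev_metrics"],
        )


class _PermissiveTagIndex(dict):
    """Tag index that maps unseen tags to O — prediction inputs may carry
    placeholder tags."""

    def __init__(self, base: dict):
        super().__init__(base)
        self._o = base["O"]

    def __getitem__(self, key):
        return super().get(key, self._o)


def _config_to_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def _config_from_dict(d: dict) -> dict:
    out = dict(d)
    for key in ("granularities", "lsfe_channels", "decoder_channels", "adam_betas"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def train(
    train_docs: list[AnnotatedDocument],
    config: ModelConfig,
    rng_seed: int,
    dev_docs: list[AnnotatedDocument] | None = None,
    catalog: EntityTypeCatalog | None = None,
    verbose: bool = False,
) -> MTCGANResults:
    """Alternating minibatch adversarial training (k discriminator steps per
    generator step); returns fitted parameters and per-epoch history."""
    model = MTCGAN(train_docs, dev_docs, catalog=catalog, config=config)
    return model.fit(rng_seed=rng_seed, verbose=verbose)
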