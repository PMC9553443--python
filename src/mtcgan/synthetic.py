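"""Synthetic annotated corpora with the statistical structure the model
assumes: character-level text with no whitespace, a chapter -> paragraph ->
sentence hierarchy, 19 entity types with controllable frequency skew,
multi-character entities, and sparse/irregular entity placement.

Characters are synthetic CJK codepoints standing in for Chinese characters;
the model is character-agnostic, so no lexical resources are required.  Two
regimes are first class:

* easy / separable: every entity type draws its surface n-grams from a
  private character pool disjoint from the background alphabet and from all
  other types, so the mapping from surface to type is unambiguous;
* hard / ambiguous: a configurable fraction of lexicon entries is shared
  between two types (the surface alone cannot decide the type), and each
  planted entity optionally drops a type-specific cue character elsewhere in
  the sentence, so only sentence-level context can disambiguate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import EntityTypeCatalog, default_catalog
from .corpus import AnnotatedDocument

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "build_lexicons",
    "generate",
    "make_skewed_pair",
    "subsample",
    "easy_config",
    "hard_config",
]

_BASE_CODEPOINT = 0x4E00
_TYPE_POOL = 8  # private characters per entity type (last one is the cue)


@dataclass
class SynthConfig:
    n_chapters: int = 5
    paragraphs_per_chapter: int = 5
    sentences_per_paragraph: int = 4
    sentence_length: tuple[int, int] = (8, 14)
    alphabet_size: int = 30
    weights: tuple[float, ...] = ()  # 19 non-negative type weights
    entity_density: float = 0.7  # per-slot planting probability (3 slots/sentence)
    max_entities_per_sentence: int = 3
    lexicon_size: int = 4  # entries per active type
    entry_lengths: tuple[int, ...] = (1, 2, 3)
    ambiguity_rate: float = 0.0  # fraction of entries shared between two types
    cue_rate: float = 0.0  # per-entity probability of a type cue character
    doc_type: str = "comprehensive"
    rng_seed: int = 0
    lexicon_seed: int | None = None  # fixed lexicon across realizations; None -> rng_seed

    def __post_init__(self):
        if not self.weights:
            cat = default_catalog()
            self.weights = tuple(1.0 for _ in range(cat.n_types))
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with at least one positive")
        if not 0.0 <= self.entity_density <= 1.0:
            raise ValueError("entity_density must be in [0, 1]")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        lo, hi = self.sentence_length
        if lo < max(self.entry_lengths) or hi < lo:
            raise ValueError("sentence_length range too small for lexicon entries")


@dataclass
class GroundTruth:
    spans: list  # per sentence: list of (type_label, start, end)
    counts: dict  # type_label -> planted span count

    def count_vector(self, catalog: EntityTypeCatalog) -> np.ndarray:
        return np.array([self.counts.get(l, 0) for l in catalog.labels], dtype=np.int64)


def _background_alphabet(cfg: SynthConfig) -> list[str]:
    return [chr(_BASE_CODEPOINT + i) for i in range(cfg.alphabet_size)]


def _type_pools(catalog: EntityTypeCatalog, cfg: SynthConfig) -> dict[str, list[str]]:
    pools = {}
    base = _BASE_CODEPOINT + cfg.alphabet_size
    for i, label in enumerate(catalog.labels):
        pools[label] = [chr(base + i * _TYPE_POOL + j) for j in range(_TYPE_POOL)]
    return pools


def build_lexicons(
    catalog: EntityTypeCatalog, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Per-type entity lexicons and cue characters.

    In the separable regime every entry is built from the type's private pool
    (minus the reserved cue character).  With ambiguity_rate > 0, that share
    of each type's entries is duplicated into a randomly chosen second active
    type's lexicon.
    """
    weights = np.asarray(cfg.weights, dtype=float)
    active = [catalog.labels[i] for i in range(catalog.n_types) if weights[i] > 0]
    pools = _type_pools(catalog, cfg)
    cues = {label: pools[label][-1] for label in active}
    lexicons: dict[str, list[str]] = {}
    for label in active:
        pool = pools[label][:-1]
        entries = set()
        while len(entries) < cfg.lexicon_size:
            n = int(rng.choice(cfg.entry_lengths))
            entries.add("".join(rng.choice(pool, size=n)))
        lexicons[label] = sorted(entries)
    if cfg.ambiguity_rate > 0 and len(active) > 1:
        n_shared = int(round(cfg.ambiguity_rate * cfg.lexicon_size))
        for label in active:
            others = [l for l in active if l != label]
            for entry in lexicons[label][:n_shared]:
                target = others[int(rng.integers(len(others)))]
                if entry not in lexicons[target]:
                    lexicons[target] = sorted(lexicons[target] + [entry])
    else:
        # separability guarantee: no entry may appear under two types
        seen: dict[str, str] = {}
        for label, entries in lexicons.items():
            for entry in entries:
                if entry in seen:
                    raise ValueError(
                        f"lexicon collision: {entry!r} under both {seen[entry]} and {label}"
                    )
                seen[entry] = label
    return lexicons, cues


def _make_sentence(
    cfg: SynthConfig,
    rng: np.random.Generator,
    bg: list[str],
    lexicons: dict[str, list[str]],
    cues: dict[str, str],
    active: list[str],
    probs: np.ndarray,
) -> tuple[list, list]:
    lo, hi = cfg.sentence_length
    length = int(rng.integers(lo, hi + 1))
    k = int(rng.binomial(cfg.max_entities_per_sentence, cfg.entity_density))
    picks: list[tuple[str, str]] = []
    for _ in range(k):
        label = active[int(rng.choice(len(active), p=probs))]
        entry = lexicons[label][int(rng.integers(len(lexicons[label])))]
        picks.append((label, entry))
    # drop entities that no longer fit (keeps at least one background position)
    while picks and sum(len(e) for _, e in picks) > length - 1:
        picks.pop()
    total = sum(len(e) for _, e in picks)
    n_bg = length - total
    # distribute background characters into k+1 gaps
    gaps = rng.multinomial(n_bg, np.ones(len(picks) + 1) / (len(picks) + 1))
    chars: list[str] = []
    tags: list[str] = []
    spans: list[tuple[str, int, int]] = []
    bg_positions: list[int] = []

    def emit_background(n: int):
        for _ in range(n):
            bg_positions.append(len(chars))
            chars.append(bg[int(rng.integers(len(bg)))])
            tags.append("O")

    emit_background(int(gaps[0]))
    for j, (label, entry) in enumerate(picks):
        start = len(chars)
        for idx, ch in enumerate(entry):
            chars.append(ch)
            tags.append(("B-" if idx == 0 else "I-") + label)
        spans.append((label, start, len(chars)))
        emit_background(int(gaps[j + 1]))
    # type cue characters replace background positions
    if cfg.cue_rate > 0:
        avail = list(bg_positions)
        for label, _, _ in spans:
            if avail and rng.random() < cfg.cue_rate:
                pos = avail.pop(int(rng.integers(len(avail))))
                chars[pos] = cues[label]
    return list(zip(chars, tags)), spans


def generate(
    cfg: SynthConfig, catalog: EntityTypeCatalog | None = None
) -> tuple[list[AnnotatedDocument], GroundTruth]:
    """Deterministic corpus + ground truth for a configuration."""
    catalog = catalog or default_catalog()
    if len(cfg.weights) != catalog.n_types:
        raise ValueError(f"need {catalog.n_types} weights, got {len(cfg.weights)}")
    rng = np.random.default_rng(cfg.rng_seed)
    lex_rng = np.random.default_rng(
        cfg.rng_seed if cfg.lexicon_seed is None else cfg.lexicon_seed
    )
    bg = _background_alphabet(cfg)
    lexicons, cues = build_lexicons(catalog, cfg, lex_rng)
    weights = np.asarray(cfg.weights, dtype=float)
    active = [catalog.labels[i] for i in range(catalog.n_types) if weights[i] > 0]
    probs = weights[weights > 0]
    probs = probs / probs.sum()

    chapters = []
    all_spans = []
    counts: dict[str, int] = {}
    for _ in range(cfg.n_chapters):
        paragraphs = []
        for _ in range(cfg.paragraphs_per_chapter):
            sentences = []
            for _ in range(cfg.sentences_per_paragraph):
                sent, spans = _make_sentence(cfg, rng, bg, lexicons, cues, active, probs)
                sentences.append(sent)
                all_spans.append(spans)
                for label, _, _ in spans:
                    counts[label] = counts.get(label, 0) + 1
            paragraphs.append(sentences)
        chapters.append(paragraphs)
    doc = AnnotatedDocument(chapters=chapters, doc_type=cfg.doc_type)
    return [doc], GroundTruth(spans=all_spans, counts=counts)


def make_skewed_pair(
    cfg: SynthConfig,
    weights_b: tuple[float, ...],
    catalog: EntityTypeCatalog | None = None,
):
    """Two corpora identical in everything (incl. text backbone seed) except
    the type-frequency weight vector."""
    if tuple(cfg.weights) == tuple(weights_b):
        raise ValueError("the two weight vectors must differ")
    corpus_a = generate(cfg, catalog)
    corpus_b = generate(replace(cfg, weights=tuple(weights_b)), catalog)
    return corpus_a, corpus_b


def subsample(
    corpus: list[AnnotatedDocument], fraction: float, rng_seed: int
) -> list[AnnotatedDocument]:
    """Sentence-level sampling without replacement; hierarchy preserved,
    empty paragraphs/chapters pruned."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return corpus
    n_total = sum(doc.n_sentences() for doc in corpus)
    n_keep = int(round(fraction * n_total))
    rng = np.random.default_rng(rng_seed)
    keep = set(rng.choice(n_total, size=n_keep, replace=False).tolist())
    out = []
    idx = 0
    for doc in corpus:
        chapters = []
        for paragraphs in doc.chapters:
            new_paras = []
            for sentences in paragraphs:
                kept = []
                for sent in sentences:
                    if idx in keep:
                        kept.append(sent)
                    idx += 1
                if kept:
                    new_paras.append(kept)
            if new_paras:
                chapters.append(new_paras)
        out.append(AnnotatedDocument(chapters=chapters, doc_type=doc.doc_type))
    return out


# -- study-condition presets ------------------------------------------------------


def easy_config(
    n_sentences: int = 500, rng_seed: int = 0, catalog: EntityTypeCatalog | None = None
) -> SynthConfig:
    """Separable regime: 5 active entity types (the medical-case set), private
    character pools, no ambiguity.  Sentence counts are rounded up to whole
    chapters of 5 paragraphs x 4 sentences."""
    catalog = catalog or default_catalog()
    active = {"ZY", "ZZ", "MX", "SX", "FJ"}
    weights = tuple(1.0 if l in active else 0.0 for l in catalog.labels)
    per_chapter = 5 * 4
    return SynthConfig(
        n_chapters=max(1, -(-n_sentences // per_chapter)),
        paragraphs_per_chapter=5,
        sentences_per_paragraph=4,
        sentence_length=(8, 14),
        alphabet_size=30,
        weights=weights,
        entity_density=0.7,
        ambiguity_rate=0.0,
        cue_rate=0.0,
        doc_type="medical_cases",
        rng_seed=rng_seed,
        lexicon_seed=7,
    )


def hard_config(
    n_sentences: int = 120, rng_seed: int = 0, catalog: EntityTypeCatalog | None = None
) -> SynthConfig:
    """Ambiguous, sparse regime: 10 active types with skewed frequencies, 40%
    of lexicon entries shared between two types, sentence-level cue characters
    carrying the disambiguating context."""
    catalog = catalog or default_catalog()
    active = ["ZY", "ZZ", "MX", "SX", "FJ", "BY", "JB", "ZH", "YX", "GJ"]
    skew = {l: 1.0 / (r + 1) for r, l in enumerate(active)}  # Zipf-like
    weights = tuple(skew.get(l, 0.0) for l in catalog.labels)
    per_chapter = 5 * 4
    return SynthConfig(
        n_chapters=max(1, -(-n_sentences // per_chapter)),
        paragraphs_per_chapter=5,
        sentences_per_paragraph=4,
        sentence_length=(8, 12),
        alphabet_size=40,
        weights=weights,
        entity_density=0.4,
        ambiguity_rate=0.4,
        cue_rate=0.9,
        doc_type="comprehensive",
        rng_seed=rng_seed,
        lexicon_seed=7,
    )
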