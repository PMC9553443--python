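"""Seed of entity distribution features.

A corpus-type prior for the generator: each of the 19 entity types gets a
fixed initial embedding v_i (independent of corpus type); the annotated
corpus supplies per-type span frequencies f_i, normalised to probabilities
p_i = f_i / sum(f); the seed is the splice [p_1 v_1 || p_2 v_2 || ... ||
p_19 v_19].  Corpora with different type skews therefore produce different
seeds, while scaling all frequencies by a constant leaves the seed unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import EntityTypeCatalog
from .corpus import AnnotatedDocument, iter_sentences

__all__ = [
    "SeedVector",
    "init_entity_vectors",
    "count_frequencies",
    "probabilities",
    "build_seed",
]


@dataclass
class SeedVector:
    data: np.ndarray  # length n_types * d_emb
    d_emb: int
    corpus_type: str = "comprehensive"

    def block(self, i: int) -> np.ndarray:
        return self.data[i * self.d_emb : (i + 1) * self.d_emb]


def init_entity_vectors(
    catalog: EntityTypeCatalog,
    d_emb: int,
    rng_seed: int,
    unit_norm: bool = True,
) -> np.ndarray:
    """One initial vector per entity type, deterministic in `rng_seed`.

    The vectors are type-identity embeddings shared across corpus types;
    externally trained vectors of the same shape may be substituted.
    """
    if d_emb <= 0:
        raise ValueError("d_emb must be positive")
    rng = np.random.default_rng(rng_seed)
    v = rng.normal(size=(catalog.n_types, d_emb))
    if unit_norm:
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def count_frequencies(
    corpus: list[AnnotatedDocument], catalog: EntityTypeCatalog
) -> np.ndarray:
    """Number of gold entity spans per type (each B-X opens one span)."""
    f = np.zeros(catalog.n_types, dtype=np.int64)
    idx = {label: i for i, label in enumerate(catalog.labels)}
    for sent in iter_sentences(corpus):
        for _, tag in sent:
            if tag.startswith("B-"):
                f[idx[tag[2:]]] += 1
    return f


def probabilities(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if total == 0:
        raise ValueError("no entities in corpus: all frequencies are zero")
    return f / total


def build_seed(
    catalog: EntityTypeCatalog,
    corpus: list[AnnotatedDocument],
    d_emb: int,
    rng_seed: int,
    corpus_type: str = "comprehensive",
    mode: str = "distribution",
    vectors: np.ndarray | None = None,
) -> SeedVector:
    """Construct the probability-weighted, spliced seed vector.

    mode="random" replaces every p_i*v_i block with a fresh random block of
    matching scale (the ablation baseline that carries no distribution
    information).
    """
    v = vectors if vectors is not None else init_entity_vectors(catalog, d_emb, rng_seed)
    if v.shape != (catalog.n_types, d_emb):
        raise ValueError(f"expected vectors of shape {(catalog.n_types, d_emb)}")
    if mode == "random":
        rng = np.random.default_rng(rng_seed + 1)
        blocks = rng.normal(scale=1.0 / catalog.n_types, size=(catalog.n_types, d_emb))
        return SeedVector(blocks.reshape(-1).copy(), d_emb, corpus_type)
    if mode != "distribution":
        raise ValueError(f"unknown seed mode {mode!r}")
    p = probabilities(count_frequencies(corpus, catalog))
    data = (p[:, None] * v).reshape(-1)
    return SeedVector(data.copy(), d_emb, corpus_type)
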