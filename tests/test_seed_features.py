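"""Catalog integrity and the entity-distribution seed construction."""

import numpy as np
import pytest

from mtcgan import (
    AnnotatedDocument,
    build_seed,
    count_frequencies,
    generate,
    init_entity_vectors,
    probabilities,
)
from mtcgan.catalog import EntityType, EntityTypeCatalog
from mtcgan.synthetic import SynthConfig, easy_config


def test_catalog_has_19_unique_types_and_40_tags(catalog):
    assert catalog.n_types == 19
    assert len(set(catalog.labels)) == 19
    assert catalog.n_tags == 40
    tags = catalog.tag_list()
    assert tags[0] == "<pad>" and tags[1] == "O" and len(tags) == 40


def test_catalog_doc_type_views(catalog):
    for dt in ("canon", "medical_cases", "herbal", "comprehensive"):
        labels = catalog.labels_for_doc_type(dt)
        assert labels and set(labels) <= set(catalog.labels)
    assert "ZZ" in catalog.labels_for_doc_type("medical_cases")
    with pytest.raises(ValueError):
        catalog.labels_for_doc_type("poetry")


def test_catalog_json_round_trip(tmp_path, catalog):
    p = tmp_path / "catalog.json"
    catalog.to_json(p)
    assert EntityTypeCatalog.from_json(p) == catalog


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError):
        EntityTypeCatalog(types=[EntityType("a", "X"), EntityType("b", "X")])


def test_initial_vectors_deterministic_and_unit_norm(catalog):
    a = init_entity_vectors(catalog, d_emb=8, rng_seed=5)
    b = init_entity_vectors(catalog, d_emb=8, rng_seed=5)
    c = init_entity_vectors(catalog, d_emb=8, rng_seed=6)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)
    np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)


def test_span_frequency_counting(catalog):
    doc = AnnotatedDocument(
        chapters=[[[[("a", "B-ZZ"), ("b", "I-ZZ"), ("c", "O"), ("d", "B-ZZ")]]]]
    )
    f = count_frequencies([doc], catalog)
    assert f[catalog.index("ZZ")] == 2 and f.sum() == 2
    assert count_frequencies([], catalog).sum() == 0


def test_planted_counts_recovered_exactly(catalog):
    cfg = SynthConfig(n_chapters=3, rng_seed=11)
    docs, gt = generate(cfg, catalog)
    f = count_frequencies(docs, catalog)
    np.testing.assert_array_equal(f, gt.count_vector(catalog))


def test_probability_normalisation(catalog):
    p = probabilities(np.ones(19))
    np.testing.assert_allclose(p, 1 / 19)
    p = probabilities(np.array([3, 1] + [0] * 17))
    np.testing.assert_allclose(p[:2], [0.75, 0.25])
    rng = np.random.default_rng(0)
    for _ in range(20):
        f = rng.integers(0, 50, size=19)
        if f.sum() == 0:
            continue
        assert abs(probabilities(f).sum() - 1.0) < 1e-12
    with pytest.raises(ValueError):
        probabilities(np.zeros(19))


def test_seed_block_structure(catalog):
    docs, _ = generate(easy_config(40, rng_seed=2), catalog)
    sv = build_seed(catalog, docs, d_emb=6, rng_seed=9)
    assert sv.data.shape == (19 * 6,)
    v = init_entity_vectors(catalog, 6, 9)
    p = probabilities(count_frequencies(docs, catalog))
    for i in range(19):
        np.testing.assert_allclose(sv.block(i), p[i] * v[i], atol=1e-12)
    # zero-frequency types give all-zero blocks
    inactive = [i for i in range(19) if p[i] == 0]
    assert inactive
    for i in inactive:
        assert np.all(sv.block(i) == 0)


def test_seed_frequency_scaling_invariance(catalog):
    """Duplicating the corpus (x2 every frequency) leaves the seed unchanged."""
    docs, _ = generate(easy_config(40, rng_seed=2), catalog)
    doubled = docs + docs
    a = build_seed(catalog, docs, d_emb=6, rng_seed=9)
    b = build_seed(catalog, doubled, d_emb=6, rng_seed=9)
    np.testing.assert_allclose(a.data, b.data, atol=1e-12)


def test_skewed_corpora_give_distinct_seeds(catalog):
    from mtcgan import make_skewed_pair

    cfg = easy_config(60, rng_seed=4)
    wb = list(cfg.weights)
    # move all mass onto one active type
    active = [i for i, w in enumerate(wb) if w > 0]
    wb = [0.0] * len(wb)
    wb[active[0]] = 1.0
    (docs_a, gt_a), (docs_b, gt_b) = make_skewed_pair(cfg, tuple(wb), catalog)
    fa = gt_a.count_vector(catalog)
    fb = gt_b.count_vector(catalog)
    assert (fb > 0).sum() == 1  # all mass on one type as planted
    sa = build_seed(catalog, docs_a, d_emb=6, rng_seed=9)
    sb = build_seed(catalog, docs_b, d_emb=6, rng_seed=9)
    cos = sa.data @ sb.data / (np.linalg.norm(sa.data) * np.linalg.norm(sb.data))
    assert cos < 0.999  # seeds reflect the differing skews
    assert not np.allclose(sa.data, sb.data)


def test_random_seed_mode_ignores_distribution(catalog):
    docs, _ = generate(easy_config(40, rng_seed=2), catalog)
    dist = build_seed(catalog, docs, d_emb=6, rng_seed=9, mode="distribution")
    rand = build_seed(catalog, docs, d_emb=6, rng_seed=9, mode="random")
    assert not np.allclose(dist.data, rand.data)
    # random mode is deterministic in the seed too
    rand2 = build_seed(catalog, docs, d_emb=6, rng_seed=9, mode="random")
    np.testing.assert_array_equal(rand.data, rand2.data)
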