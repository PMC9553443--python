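# mtcgan

Conditional-GAN named entity recognition for small annotated corpora of
traditional Chinese medicine (TCM) literature.

## The problem

Classical TCM texts (herbals, medical case collections, canonical treatises)
carry entities — herbs, symptoms, pulse and tongue descriptions, formulas,
syndromes — whose extraction is the first step of knowledge-base
construction. Annotated corpora in this domain are small and expensive:
conventional deep sequence labellers underperform, and dictionary-based
methods need resources that often do not exist. This package implements a
multigranularity, conditional-GAN approach to character-level NER designed
for exactly this low-resource setting, together with a synthetic corpus
generator that reproduces the statistical structure of such texts so every
stage is testable without any external data.

## The model

Text X = {x_0,…,x_n} (characters) is mapped to BIO tags over 19 entity
types (a 40-tag space). The **generator** combines:

* a multigranularity text feature encoder — GRU character encoder (h_c),
  6-layer / 8-head self-attention sentence and paragraph encoders
  (h_s, a_s, h_p, a_p with Z_h = softmax(Q_h K_hᵀ/√d_k)V_h), and a CNN
  chapter encoder (h_a);
* an entity-distribution **seed** for the corpus type: with span frequencies
  f_i and probabilities p_i = f_i/Σ_j f_j, the seed is the splice
  [p_1 v_1 ‖ … ‖ p_19 v_19] over fixed type embeddings v_i;
* a conditionally enhanced 1-D U-Net: a 6-level convolutional encoder over
  the seed (skip connections to a mirrored 6-level transposed-convolution
  decoder) plus a fusion layer that builds the condition Y per position from
  h_c, h_s + h_p, h_a and the U-Net bottleneck.

The fused attention data A = [a_s ‖ a_p] replaces the white noise of a
plain conditional GAN as the generator's main input. The **discriminator**
(seven 1-D conv layers, layer norm + LeakyReLU, sigmoid) receives generated
or real label sequences conditioned on the real labels L — generator and
discriminator see *different* conditions. Training alternates k = 1
discriminator steps with one generator step (Adam, lr decay per epoch),
minimising

    min_G max_D  E[log D(L|L)] + E[log(1 − D(G(A|Y)|L))],
    loss_G = CrossEntropy + λ · E[log(1 − D(G(A|Y)|L))].

A linear-chain CRF fitted post hoc on the generator's label scores converts
score sequences to tag sequences (Viterbi), and predictions are scored with
span-exact entity-level precision/recall/F1.

All networks run on a small, gradient-checked reverse-mode autodiff engine
over NumPy included in the package (`mtcgan.autodiff`); no deep-learning
framework is required.

## Worked example

```python
from mtcgan import MTCGAN, desk_profile, easy_config, generate

train, _ = generate(easy_config(n_sentences=200, rng_seed=0))
dev, _ = generate(easy_config(n_sentences=60, rng_seed=1000))

model = MTCGAN(train, dev, config=desk_profile(epochs=10))
results = model.fit(rng_seed=0)
print(results.summary())
```

prints

```
Conditional-GAN NER results
==========================================
training sentences : 200
dev sentences      : 60
tag space          : 40 tags (19 entity types)
vocabulary         : 60 characters
granularities      : char, sentence, paragraph, chapter
main input         : attention
generator condition: Y
seed mode          : distribution
epochs x batch     : 10 x 16 (k=1, lr=0.003, decay=0.95)
rng seed           : 0
------------------------------------------
final losses       : D=1.2969 G=-0.6537
dev (CRF decode)   : P=99.18% R=98.37% F1=98.78%
```

The training corpus here is a separable synthetic "medical cases" book: 5
active entity types whose surface n-grams use characters disjoint from the
background alphabet. After 10 epochs of adversarial training the
CRF-decoded development F1 is ~98%: the generator has learned the
character→type mapping and the BIO segmentation. `results.history` is a
DataFrame with per-epoch `loss_D`, `loss_G` and greedy-decode dev metrics;
`results.predict(docs)` tags new documents; `results.save(path)` /
`MTCGANResults.load(path, train, dev)` round-trip the fitted parameters.

The same pipeline is available from the shell:

```bash
mtcgan synth --regime easy --sentences 200 --out-dir corpus/
mtcgan train --config run.yaml --out model.npz --history history.csv
mtcgan predict --config run.yaml --checkpoint model.npz \
    --input corpus/test.bio --out pred.bio
mtcgan evaluate --pred pred.bio --gold corpus/test.bio
mtcgan ablate --config run.yaml --axis seed --out ablation.csv --seeds 3
```

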