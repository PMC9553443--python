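# Methods

## Problem and model

`mtcgan` performs character-level named entity recognition (NER) on
traditional Chinese medicine (TCM) literature under small-corpus conditions.
The text is treated as a sequence-annotation problem: given characters
X = {x_0, …, x_n}, produce BIO tags L = {l_0, …, l_n} over 19 entity types
(herb, symptom, pulse, tongue, formula, …), i.e. a 40-tag space
(`<pad>`, `O`, and B-/I- pairs for each type; the padding tag occupies
index 0 and is hard-masked out of decoding).

The model is a conditional GAN whose generator produces per-position,
real-valued label score sequences and whose discriminator scores label
sequences for authenticity:

* **Multigranularity text feature encoder (MTFE).** Four encoders see the
  text at different scopes. The character encoder (CGFE) is two stacked GRU
  layers plus a fully connected tanh layer, capturing relative position
  structure: r_i = σ(W_r e_i + U_r p_{i−1}), z_i = σ(W_z e_i + U_z p_{i−1}),
  p′_i = tanh(W e_i + r_i ⊙ U p_{i−1}), p_i = (1 − z_i) ⊙ p_{i−1} + z_i ⊙ p′_i.
  The sentence and paragraph encoders (SGFE, PGFE) are stacks of six
  identical encoder layers with 8-head scaled-dot self-attention
  Z_h = softmax(Q_h K_hᵀ/√d_k) V_h; each exports the 6th layer's attention
  output a_6 ("attention data") and contextual output h_6. The paragraph
  encoder runs over the concatenated characters of a paragraph, so its
  attention crosses sentence boundaries, and its outputs are re-split to
  sentences. The chapter encoder (AGFE) is three 1-D convolutions, global
  max pooling and a fully connected layer, producing one core-feature vector
  per chapter.
* **Encoder block form.** The block is implemented exactly as specified:
  h = LayerNorm(LayerNorm(a + f) + Linear(LayerNorm(a + f))). This differs
  from the canonical Transformer block (it normalises before the
  feed-forward, uses a single linear map, and has no inner residual around
  attention); `encoder_block="canonical"` switches to the standard block.
  No positional encodings are added by default — the GRU branch is the
  positional mechanism (`positional_encoding="sinusoidal"` is available).
* **Entity-distribution seed.** Each of the 19 types gets a fixed unit-norm
  embedding v_i (seeded random by default; externally trained vectors can be
  supplied). Span frequencies f_i counted on the *training split only* give
  probabilities p_i = f_i/Σf, and the seed is the splice
  [p_1·v_1 ‖ … ‖ p_19·v_19]. Frequencies are counted as entity spans, not
  characters. A `seed_mode="random"` ablation replaces the blocks with fresh
  random vectors of matching scale.
* **Conditioned U-Net generator.** The seed is projected to a length-64
  pseudo-sequence and passed through 6 stride-2 convolution levels
  (conv + layer norm + ReLU; tanh at level 6) — the label seed feature
  encoder (LSFE) — whose per-level maps feed the mirrored 6-level
  transposed-convolution decoder (FALG) as skip connections. The fusion
  layer (MGFFL) builds the generator condition Y per text position by
  splicing the character features, the sum of projected sentence and
  paragraph features (the "contraposition addition"), the broadcast chapter
  feature and the projected U-Net bottom, followed by a learned projection.
  The decoder output is linearly interpolated from the pseudo-sequence to
  the exact text length, and a two-layer head over
  [attention data A ‖ condition Y ‖ decoded features] emits 40 scores per
  position. The main input A is the per-position splice of the sentence and
  paragraph attention data; `main_input="noise"` replaces it with Gaussian
  white noise of the same shape (the plain conditional-GAN baseline), and
  `condition="L"` swaps Y for a projection of the gold one-hot labels
  (all-zero at inference, where gold labels do not exist — the train/test
  mismatch that makes this arm weaker).
* **Discriminator.** Seven 1-D convolutions (layer norm + LeakyReLU after
  each), masked mean pooling and a sigmoid give one score in (0,1) per
  sentence. Main input: one-hot gold labels (real) or softmaxed generator
  scores (fake); conditional input: always the gold labels, spliced
  channel-wise — the "differentiated conditions" (generator sees Y,
  discriminator sees L).
* **Losses and training.** Discriminator loss
  −[E log D(real|L) + E log(1 − D(fake|L))]; generator loss
  CE + λ·E log(1 − D(fake|L)) with λ = 1 by default (λ = 0 with
  `freeze_discriminator=True` reduces training to plain supervised sequence
  labelling). Scores are clamped to [1e−7, 1−1e−7] before logs. Training
  alternates k discriminator steps (k = 1) and one generator step per
  minibatch; both nets use Adam (β = 0.9/0.999, ε = 1e−8) with gradient
  clipping at global norm 5 and multiplicative learning-rate decay 0.95 per
  epoch. A minibatch is a group of whole paragraphs (so paragraph/chapter
  context is computed once per group). Defaults: dropout 0.3, 20 epochs,
  batch ≈ 16 sentences, lr 1e−4.
* **Decoding.** A linear-chain CRF with learned transition/start/stop
  parameters is fitted *post hoc* on the trained generator's label scores by
  batched gradient ascent on the log-likelihood (emissions fixed; momentum
  0.9). Illegal BIO moves (start→I-X, O→I-X, B-X→I-Y, anything→`<pad>`) are
  hard-masked to −∞ by default. Viterbi decoding breaks ties toward the
  lowest tag index, matching the exhaustive-enumeration reference bit for
  bit. Joint CRF training inside the generator loss was considered and
  rejected: decoding is a post-processing of a trained generator here, and a
  post-hoc fit keeps the adversarial game unchanged.

## Numerical engine

No deep-learning framework is used: the networks run on a small tape-based
reverse-mode automatic-differentiation engine over NumPy
(`mtcgan.autodiff`), providing dense ops, activations, layer norm, masked
softmax, embedding gather and 1-D (transposed) convolution. Every
primitive's gradient is checked against central finite differences in the
test suite, and a liveness test asserts that gradient reaches every
parameter tensor of the generator.

## Configuration profiles

Dimensions are not dictated by the method, so three profiles are provided:

* default: d_model = 128, d_k = 16, GRU hidden 64, chapter dim 64, lr 1e−4;
* `desk_profile()`: d_model = 64, GRU hidden 32, dropout 0.1, lr 3e−3 —
  widths and learning rate matched to corpora of hundreds of sentences,
  where an epoch provides only tens of optimisation steps;
* `compact_profile()`: d_model = 32, 10 epochs, for ablation sweeps.

The per-epoch decay 0.95 presumes many steps per epoch; protocols in which
an epoch is a single minibatch (e.g. the 10-sentence memorisation check) set
`lr_decay=1.0`.

## Synthetic corpora

The generator (`mtcgan.synthetic`) emulates the statistical structure the
model assumes: character text without whitespace over a synthetic CJK
codepoint range, chapter→paragraph→sentence hierarchy, 19 types with
controllable frequency skew, multi-character entities (n-grams of length
1–3 from per-type lexicons), sparse and irregular placement (a binomial
number of entities per sentence placed at random gaps), and optional
surface ambiguity. `lexicon_seed` fixes the lexicons (the "language") while
`rng_seed` varies the realization, so train/dev splits of one corpus share
vocabulary the way pages of one book do.

Two regimes are first-class study conditions:

* easy/separable (`easy_config`): 5 active types (the medical-case set),
  per-type character pools disjoint from each other and from the background
  alphabet, density 0.7, sentence lengths 8–14 — every surface string maps
  to one type, so high F1 is achievable and the end-to-end learning check is
  meaningful;
* hard/ambiguous (`hard_config`): 10 active types with Zipf-like skew, 40%
  of lexicon entries shared between two types, density 0.4, and a
  type-specific cue character dropped elsewhere in the sentence for 90% of
  planted entities — surface alone cannot decide the type, so context
  encoders and the distribution seed have room to matter. This regime
  drives the directional ablations.

What the synthetic corpora do **not** emulate: real lexical statistics,
classical-Chinese grammar, long-range discourse structure, annotation noise
and genuine type imbalance across documents. Passing tests therefore
demonstrate that the architecture, losses, training loop and decoding are
implemented correctly and behave directionally as designed — not that the
model attains any particular accuracy on real TCM corpora.

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard desk-scale protocol: end-to-end learning
uses 500 train / 100 dev sentences, 20 epochs, k = 1, three seeds;
supervised memorisation uses 10 sentences and 200 steps; the
shrinking-fraction harness subsamples the 500-sentence corpus to
{100%, 50%, 25%} with 12 epochs; ablations run on 120 train / 60 dev hard
regime sentences with the compact profile, three seeds per arm, comparing
means.

## Known limitations

* The adversarial term uses the minimax generator loss (not the
  non-saturating variant); with λ = 1 and a weak discriminator it acts as a
  mild regulariser at this scale.
* The CRF is fitted on training-split scores only; transition estimates are
  coarse when the tag space is mostly unseen (few active types).
* Chapter features are recomputed per minibatch group; very long chapters
  make the AGFE the dominant cost.
* `condition="L"` is inherently train/test mismatched (by design, as an
  ablation arm), so its scores are not comparable to a deployable model.
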