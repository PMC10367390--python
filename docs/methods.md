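# Methods

## Model

`lexner` tags character sequences with typed entity spans by splitting the
task into two supervised branches over a shared encoder.

**Encoder.** Characters are embedded as `h¹_t = E_c[c_t] + E_p[t]`
(absolute position table optional via config).  Each of the `n_layers`
transformer layers computes multi-head attention whose logits combine four
terms — content–content, content–position, a global content bias `u·k_j`
and a global position bias `v·R_{t−j}` — all divided by `√d_k`.  The
relative-position table interleaves `sin(c_i·t)` and `cos(c_i·t)` slots
with the standard frequency schedule `c_i = 10000^(−2i/d)`; because sine is
odd, the encoding distinguishes left from right context.  `u` and `v` are
per-head learnable vectors initialised to zero, so the first forward pass
is pure content attention.

**Dictionary fusion.** Before encoding, maximum entity matching assigns
each character the id of the longest gazetteer surface covering it
(earliest start, then lowest id, on ties; id 0 = no match).  Matched
positions average their key/value projections with the entity embedding's
projections (½-weighted).  Both keys and values are fused; queries are
not.  With the position terms disabled this yields attention weights equal
to the normalised geometric mean of character-only and entity-only scores —
the identity is the module's core correctness oracle in the test suite.
There is no output projection after head concatenation; each attention
sublayer is followed by residual + layer norm and a GELU feed-forward block
(inner width `4·d_model`) with its own residual + layer norm.

**Boundary branch.** A linear projection maps encoder states to per-label
emission scores over {O, B, I}; a learnable `(L+2)×(L+2)` transition matrix
(virtual start/stop) completes a linear-chain CRF.  Training minimises the
negative log-likelihood (path score minus log-partition, computed by the
log-space forward recursion); decoding is Viterbi with first-index
tie-breaking.  Structurally invalid transitions (O→I, start→I) are
suppressed with a −10⁴ pseudo-−∞, switchable off in config.

**Type branch.** Two CNN banks with kernel widths {2, 3, 4} and 32 filters
per width ("same" zero padding) run over (a) the entity-enhanced encoder
states and (b) radical embeddings looked up from the character→radical
table (unknown characters map to a reserved radical with its own embedding
row).  Per-token activations from both banks are concatenated and passed
through a fully-connected layer to a 64-dimensional feature, classified by
an angular-margin softmax over K types + NONE: the gold logit is
`‖x‖·φ(θ_y)` with the piecewise margin function
`φ(θ) = (−1)^k cos(mθ) − 2k` for `θ ∈ [kπ/m, (k+1)π/m]`, other classes keep
`‖x‖·cos θ_j`.  `cos(mθ)` is evaluated as a Chebyshev polynomial in
`cos θ`; the interval index k is treated as a constant in the backward
pass.  For trainability the gold logit is blended as
`(λ·cos θ + φ(θ))/(1+λ)` with λ annealed from 1000 toward 5 over training
steps; with `m = 1` the loss is exactly cosine-softmax cross-entropy for
any λ.  Classifier rows are re-projected to the unit sphere after every
optimiser step.  Supervision is per token (NONE outside entities); span
types are resolved after Viterbi by majority vote over the span's per-token
argmax types, ties and all-NONE spans falling back to the highest mean
class probability.  A boundary span whose type cannot be resolved at all
(no votes and no scores) reverts to O.

**Joint objective.** `Loss = α·Loss_B + β·Loss_F`, α = β = 1 by default.
Optionally, FGM adversarial training perturbs the character embedding table
by `ε·g/‖g‖` (gradient of the joint loss), adds the loss at the perturbed
point, and restores the table exactly; a vanishing gradient skips the
perturbation.  FGM is off by default at desk scale.

## Self-training

Algorithm: fit on the labeled set L; then up to `max_rounds` times,
pseudo-label the unlabeled pool U, admit sentences with confidence ≥ τ
(capped at `per_round_cap·|U|` per round, most confident first), move them
from U to a frozen pseudo-labeled pool, and continue training with the
interpolated loss `(1−θ)·Loss_LD + θ·Loss_ULD` (labeled batches and pool
batches cycled together).  Confidence is
`exp(mean per-token log-probability of the Viterbi path)` × mean max type
probability over predicted entity tokens (1.0 when no entity is
predicted).  Rounds stop early when nothing is admitted.  Defaults:
τ = 0.9, θ = 0.3 (constant), 3 rounds, cap 20%.  Pseudo-labels are never
revised once admitted — the simplest reading of iterative augmentation.

Checkpoint selection keeps the parameters at the *first* epoch achieving
the best dev F1 (strict-improvement updates).  This makes the
supervised-vs-self-trained comparison a paired one: the self-trained model
shares the supervised fit as its initial phase, and later rounds replace
the checkpoint only when they strictly improve dev F1 — so self-training
cannot lose to its own baseline through checkpoint noise, and genuine
gains register in unsaturated regimes.

## Optimisation

Adam with differential learning rates — encoder 1e−3, heads 1e−2 (no
pre-trained encoder at desk scale) — decoupled weight decay 0.01, global
gradient-norm clipping at 2, batch size 16 with length-bucketed padded
batches.  When no dev file is supplied, a seeded 10% of the training
sentences is carved off for checkpoint selection.  All arithmetic is
float64 numpy on a hand-written reverse-mode autodiff core whose every
primitive is finite-difference checked; runs are bit-reproducible under a
fixed seed and single-threaded execution.

Desk-scale architecture defaults: `d_model = d_entity = 64`, 2 layers, 4
heads, dropout 0.1, margin m = 4.  Full-scale operation (hidden 768, 12
layers, 12 heads, dropout 0.3, max length 128) is a config override, not a
different code path.

## Synthetic data

The generator emulates the statistical structure the model exploits,
without real clinical text:

* **Gazetteer signal** — entities are planted verbatim from a generated
  dictionary (lengths 2–4, ~Poisson(1.5) entities per sentence, sentence
  lengths 12–30), so maximum matching recovers every planted span.
* **Radical signal** — each type has a characteristic radical carried by
  its characters with probability ρ (default 0.9), mimicking regularities
  like the "sickness" radical in disease characters; other characters take
  generic radicals.
* **Type ambiguity** — a fraction of surfaces (default 0.3) is drawn from a
  small shared character pool used by every type, so their type is
  unreadable from characters or radicals and only the dictionary-id context
  resolves it.  Ambiguity is the default condition because ambiguous
  terminology is the problem the dictionary-fusion mechanism exists for.
* Background characters come from a sub-vocabulary disjoint from all entity
  pools, keeping desk-scale learning feasible; entities never overlap,
  never cross sentence boundaries, and are separated by at least one
  background character.

What the generator does **not** model: real clinical language (negation,
section structure, abbreviations), nested entities, boundary ambiguity
between entity and background characters, or label noise.  Passing tests
therefore demonstrate that the implementation learns the mechanisms it
claims to exploit — not that it reaches any particular accuracy on real
EMR corpora.

## Experiment designs in the test suite

* **End-to-end recovery**: corpus seed 7 (500/100/100 train/dev/test, 4
  types, 40 surfaces, ρ = 0.9), desk model, 30 epochs; held-out entity F1
  is asserted ≥ 0.90.
* **Self-training direction**: 30% of the same corpus labeled (3 seeds);
  supervised baseline (30 epochs) vs the same fit continued by 3
  self-training rounds (τ = 0.9, θ = 0.3, 6 epochs each); mean test F1 of
  the self-trained model must match or exceed the baseline.  At these
  sizes the baseline nearly saturates, so the expected gain is ≈ 0; the
  test checks the direction.
* **Fusion ablation**: ambiguity 0.5 over a 3-character shared pool, 60
  surfaces, 200 training sentences, 10 epochs, 3 seeds.  The dictionary id
  and the surface string are in bijection, so fusion helps exactly where
  surface memorisation is hard — the tiny shared pool makes ambiguous
  surfaces mutually confusable at the n-gram level.  Mean F1 with fusion
  must exceed mean F1 without.
* **Radical ablation**: vocabulary of 800 characters (so entity characters
  are rare), 120 surfaces, 150 training sentences, ρ = 0.95, 10 epochs, 3
  seeds; mean gold-span type accuracy with the radical branch must exceed
  the branch-ablated mean.

Problem sizes throughout are chosen so the full suite runs in minutes on
one CPU; they are desk-scale analogues, not reproductions of benchmark
scores on CCKS-style corpora (out of scope — those require external data
and large-scale pre-training).

## Numerical choices and edge cases

* CRF recursion entirely in log-space; the partition can never overflow.
* Attention uses an additive −10⁹ mask for padded positions; softmax by
  shifted log-sum-exp.
* A-Softmax guards zero-norm features (ε inside the norm) and clips
  cosines to ±(1−10⁻⁷) before the arccos.
* Viterbi ties resolve to the lowest label index; matching ties to the
  earliest start then lowest id; all tie-breaks are deterministic.
* Orphan I tags in raw CRF output (possible only with constraints
  disabled) open a new span during recombination; corpus reading offers
  `strict` (raise) and `repair` (promote I→B) schemes.
* Checkpoints are a `.npz` of parameter tables plus a JSON sidecar with
  config, vocabularies, dictionary, radical table and seed.

## Known limitations

* The surface↔id bijection means dictionary fusion cannot inject
  information absent from the characters; its value is sample efficiency
  and disambiguation, which the ablation corpora are designed to expose.
* Radical embeddings are trainable from scratch; loading pre-trained
  sub-character vectors is a hook, not a shipped feature.
* No nested entities, no BIOES variant, no PGD adversarial training, no
  mixed precision, no cross-validation driver — all deliberately out of
  scope.
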