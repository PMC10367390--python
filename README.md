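# lexner

Dictionary-fused, radical-aware **dual-branch named-entity recognition** for
clinical character sequences (Chinese-EMR-style text), with a
confidence-filtered self-training mode for low-label regimes.

Clinical notes are dense with domain terminology whose boundaries and
categories are hard to read off characters alone: the same surface can name
a drug or a disease, and rare characters appear in few training examples.
`lexner` attacks this with three mechanisms working together:

1. **Entity-dictionary fusion inside self-attention.** A gazetteer of known
   entity surfaces is matched against each sentence by *maximum entity
   matching* (every character gets the id of the longest dictionary surface
   covering it, 0 if none).  For a matched character the attention keys and
   values become the average of the character projection and the entity
   embedding projection:

       k_t = ½ (h_t W_hk + E_ent[e_t] W_ek),   v_t analogously,

   so the attention row at an entity position is exactly the normalised
   geometric mean √(sᶜ·sᵉ) of character-only and entity-only attention
   scores.

2. **A direction-aware character transformer.** Attention logits are

       A(t,j) = [ q_t·k_j + q_t·R_{t−j} + u·k_j + v·R_{t−j} ] / √d_k

   with a signed sinusoidal relative-position table R (sine slots are odd
   in the offset, so left and right context score differently) and
   learnable per-head biases u, v.

3. **Two decoding branches.** Entity *boundaries* are decoded by a
   linear-chain CRF over {B, I, O} (forward-recursion likelihood, Viterbi
   decoding).  Entity *types* are classified per token by two CNN banks
   (kernel widths 2/3/4) — one over the entity-enhanced encoder states, one
   over **radical embeddings** (the semantic sub-character component, e.g.
   the "sickness" radical shared by disease characters) — through an
   angular-margin (A-Softmax) objective.  The global loss is
   `α·Loss_B + β·Loss_F`, and spans are recombined by majority vote with
   probability tie-breaks.

Semi-supervised training follows the classic self-training loop: fit on the
labeled set, pseudo-label the unlabeled pool, admit sentences whose
confidence (CRF path probability × mean entity-token type probability)
clears a threshold τ, and continue training on the mixture
`(1−θ)·Loss_LD + θ·Loss_ULD`.

Everything runs on a small numpy reverse-mode autodiff core (`lexner.autodiff`)
— no deep-learning framework required — and every experiment is exercised on
synthetic corpora the package generates itself (planted dictionary entities,
type-correlated radicals, controllable surface ambiguity).

## Worked example

```python
from lexner import DualBranchNER, ModelConfig, TrainConfig, SynthConfig, generate

ds = generate(SynthConfig(n_train=100, n_dev=30, n_test=50, seed=7))
model = DualBranchNER.from_corpus(ds.train, ds.dictionary, ds.radical_table,
                                  ModelConfig(), seed=0)
results = model.fit(ds.train, ds.dev, TrainConfig(epochs=8, seed=0))
print(results.summary())
print("test F1:", model.evaluate(ds.test)["f1"])
```

prints (abridged):

```
Dual-branch NER fit
==============================================
 epoch    loss_B    loss_F   dev F1
     0   12.8412    1.0324   0.0000
     1    3.2536    0.3486   0.7805
     2    0.3174    0.0416   1.0000
     ...
best dev F1 1.0000 at epoch 2  (3.8s)
test F1: 1.0
```

`loss_B` is the mean CRF negative log-likelihood of the gold boundary
paths, `loss_F` the mean angular-margin type loss; dev F1 is entity-level
(exact span + type match).  On this easy planted corpus the model recovers
every held-out entity after two epochs.

The same object drives the semi-supervised mode:

```python
from lexner import SelfTrainConfig, degrade_labels
labeled, unlabeled = degrade_labels(ds.train, 0.3, seed=0)
model = DualBranchNER.from_corpus(labeled, ds.dictionary, ds.radical_table, seed=0)
res = model.fit_semisupervised(labeled, unlabeled,
                               SelfTrainConfig(tau=0.9, theta=0.3, max_rounds=3),
                               TrainConfig(epochs=12, seed=0), ds.dev)
```

A `lexner` console script exposes the same pipeline from the shell
(`simulate`, `train`, `selftrain`, `predict`, `eval`), configured by one
YAML file with dotted `--set` overrides; every run writes a reproducibility
manifest and a JSONL metric log.

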