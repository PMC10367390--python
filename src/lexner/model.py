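"""The dual-branch tagger as a fittable model object.

:class:`DualBranchNER` bundles the character transformer encoder (with
dictionary fusion), the CRF boundary branch and the radical-CNN /
A-Softmax type branch behind a statsmodels-style surface: build it from a
corpus with :meth:`from_corpus`, call :meth:`fit` (or
:meth:`fit_semisupervised`) to get a :class:`~lexner.training.FitResults`,
then :meth:`predict` / :meth:`evaluate` on new sentences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, Parameter, no_grad
from .corpus_io import (BranchLabels, EntityDictionary, LabeledSentence,
                        NONE_TYPE, RadicalTable, entity_f1, extract_spans,
                        merge_labels, split_labels)
from .encoder import EncoderConfig, EncoderParams, encode
from .heads import (BOUNDARY_LABELS, CrfParams, TypeHeadParams, asoftmax_loss,
                    crf_log_partition_batch, crf_path_log_prob,
                    crf_path_score_batch, radical_features, type_probabilities,
                    viterbi_decode)
from .matching import match_entities

PAD, UNK = 0, 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (desk-scale defaults).

    Full-scale operation (hidden 768, 12 layers, 12 heads, dropout 0.3,
    max length 128) is reached by overriding these fields.
    """

    d_model: int = 64
    d_entity: int = 64
    n_layers: int = 2
    n_heads: int = 4
    dropout: float = 0.1
    max_len: int = 160
    use_entity_fusion: bool = True
    use_relative_position: bool = True
    use_absolute_position: bool = True
    use_radical_branch: bool = True
    conv_filters: int = 32
    kernel_widths: tuple = (2, 3, 4)
    type_feature_dim: int = 64
    margin: int = 4
    forbid_invalid_transitions: bool = True

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            d_model=self.d_model, d_entity=self.d_entity,
            n_layers=self.n_layers, n_heads=self.n_heads,
            dropout=self.dropout, max_len=self.max_len,
            use_entity_fusion=self.use_entity_fusion,
            use_relative_position=self.use_relative_position,
            use_absolute_position=self.use_absolute_position)


class DualBranchNER:
    """Dictionary-fused dual-branch tagger over character sequences."""

    def __init__(self, config: ModelConfig, char_vocab: dict,
                 dictionary: EntityDictionary, radical_table: RadicalTable,
                 type_names: Sequence[str], seed: int = 0):
        self.config = config
        self.char2id = dict(char_vocab)
        self.dictionary = dictionary
        self.radical_table = radical_table
        self.types = [NONE_TYPE] + sorted(t for t in type_names if t != NONE_TYPE)
        self.rad2id = {"<PAD>": 0}
        for rad in radical_table.radicals:
            self.rad2id.setdefault(rad, len(self.rad2id))
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.enc = EncoderParams.init(config.encoder_config(), len(self.char2id),
                                      len(dictionary), rng)
        self.crf = CrfParams.init(rng, config.forbid_invalid_transitions)
        self.emis_W = Parameter(rng.normal(0, 0.02, (config.d_model, len(BOUNDARY_LABELS))),
                                "emis_W")
        self.emis_b = Parameter(np.zeros(len(BOUNDARY_LABELS)), "emis_b")
        self.typehead = TypeHeadParams.init(
            config.d_model, len(self.rad2id), len(self.types), rng,
            widths=config.kernel_widths, n_filters=config.conv_filters,
            d_feat=config.type_feature_dim, margin=config.margin)
        self._dropout_rng = np.random.default_rng(seed + 1)
        self._ent_cache: dict = {}

    # -- construction --------------------------------------------------------
    @classmethod
    def from_corpus(cls, train: Sequence[LabeledSentence],
                    dictionary: EntityDictionary, radical_table: RadicalTable,
                    config: ModelConfig | None = None, seed: int = 0) -> "DualBranchNER":
        if not train:
            raise ValueError("training corpus is empty")
        config = config or ModelConfig()
        vocab = {"<PAD>": PAD, "<UNK>": UNK}
        for sent in train:
            for ch in sent.chars:
                vocab.setdefault(ch, len(vocab))
        for surface, _t in dictionary.entries:
            for ch in surface:
                vocab.setdefault(ch, len(vocab))
        types = {t for _s, t in dictionary.entries}
        for sent in train:
            for _a, _b, t in extract_spans(sent.labels):
                types.add(t)
        return cls(config, vocab, dictionary, radical_table, sorted(types), seed)

    # -- parameter bookkeeping ----------------------------------------------
    def encoder_parameters(self) -> list[Parameter]:
        return self.enc.parameters()

    def head_parameters(self) -> list[Parameter]:
        return [self.crf.trans, self.emis_W, self.emis_b] + self.typehead.parameters()

    def parameters(self) -> list[Parameter]:
        return self.encoder_parameters() + self.head_parameters()

    def state_dict(self) -> dict:
        return {p.name or f"p{i}": p.data.copy()
                for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[p.name or f"p{i}"]

    # -- numericalisation ----------------------------------------------------
    def _entity_tags(self, chars: tuple) -> list[int]:
        tags = self._ent_cache.get(chars)
        if tags is None:
            tags = match_entities(chars, self.dictionary)
            self._ent_cache[chars] = tags
        return tags

    def numericalize(self, chars: Sequence[str]):
        chars = tuple(chars)
        cid = [self.char2id.get(c, UNK) for c in chars]
        eid = self._entity_tags(chars)
        rid = [self.rad2id.get(self.radical_table.lookup(c), 0) for c in chars]
        return cid, eid, rid

    def make_batches(self, sentences: Sequence, batch_size: int,
                     shuffle_rng: np.random.Generator | None = None) -> list[dict]:
        """Length-bucketed padded batches.

        ``sentences`` holds LabeledSentence (labels included in the batch)
        or bare character lists (inference).
        """
        def chars_of(s):
            return s.chars if isinstance(s, LabeledSentence) else s

        order = np.argsort([len(chars_of(s)) for s in sentences], kind="stable")
        chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
        if shuffle_rng is not None:
            shuffle_rng.shuffle(chunks)
        batches = []
        for chunk in chunks:
            group = [sentences[i] for i in chunk]
            lengths = np.array([len(chars_of(s)) for s in group])
            T = int(lengths.max())
            B = len(group)
            batch = {"index": np.asarray(chunk), "lengths": lengths,
                     "char_ids": np.zeros((B, T), dtype=np.intp),
                     "ent_ids": np.zeros((B, T), dtype=np.intp),
                     "rad_ids": np.zeros((B, T), dtype=np.intp),
                     "mask": (np.arange(T)[None, :] < lengths[:, None]).astype(float)}
            labeled = all(isinstance(s, LabeledSentence) for s in group)
            if labeled:
                batch["boundary"] = np.zeros((B, T), dtype=np.intp)
                batch["type_ids"] = np.zeros((B, T), dtype=np.intp)
            for bi, s in enumerate(group):
                cid, eid, rid = self.numericalize(chars_of(s))
                L = len(cid)
                batch["char_ids"][bi, :L] = cid
                batch["ent_ids"][bi, :L] = eid
                batch["rad_ids"][bi, :L] = rid
                if labeled:
                    br = split_labels(s)
                    batch["boundary"][bi, :L] = [BOUNDARY_LABELS.index(b)
                                                 for b in br.boundary]
                    batch["type_ids"][bi, :L] = [self.types.index(t) for t in br.types]
            batches.append(batch)
        return batches

    # -- forward / losses ----------------------------------------------------
    def _encode_batch(self, batch: dict, train_mode: bool) -> Tensor:
        return encode(batch["char_ids"], batch["ent_ids"], self.enc,
                      self.config.encoder_config(), pad_mask=batch["mask"],
                      train_mode=train_mode, rng=self._dropout_rng)

    def _type_features(self, hidden: Tensor, batch: dict) -> Tensor:
        return radical_features(hidden, batch["rad_ids"], self.typehead,
                                use_radical_branch=self.config.use_radical_branch)

    def loss_batch(self, batch: dict, lam: float = 0.0,
                   train_mode: bool = True) -> tuple[Tensor, Tensor, Tensor]:
        """(boundary NLL, type loss), both averaged over the batch."""
        hidden = self._encode_batch(batch, train_mode)
        emissions = hidden @ self.emis_W + self.emis_b
        trans = self.crf.effective()
        nll = crf_log_partition_batch(emissions, trans, batch["lengths"]) \
            - crf_path_score_batch(emissions, trans, batch["boundary"],
                                   batch["lengths"])
        loss_b = nll.mean()
        feats = self._type_features(hidden, batch)
        bi, ti = np.nonzero(batch["mask"] > 0)
        flat = feats[(bi, ti)]
        labels = batch["type_ids"][bi, ti]
        loss_f = asoftmax_loss(flat, labels, self.typehead.cls_W,
                               m=self.config.margin, lam=lam)
        return loss_b, loss_f

    # -- inference -----------------------------------------------------------
    def _decode_batch(self, batch: dict):
        with no_grad():
            hidden = self._encode_batch(batch, train_mode=False)
            emissions = (hidden @ self.emis_W + self.emis_b).data
            feats = self._type_features(hidden, batch)
            B, T = batch["char_ids"].shape
            probs = type_probabilities(
                feats.reshape(B * T, -1), self.typehead.cls_W).reshape(B, T, -1)
        out = []
        for bi in range(B):
            L = int(batch["lengths"][bi])
            path = viterbi_decode(emissions[bi, :L], self.crf)
            boundary = [BOUNDARY_LABELS[i] for i in path]
            tok_types = [self.types[int(np.argmax(probs[bi, t]))] for t in range(L)]
            labels = merge_labels(BranchLabels(boundary=boundary, types=tok_types),
                                  (probs[bi, :L], self.types))
            conf = None
            out.append({"index": int(batch["index"][bi]), "labels": labels,
                        "emissions": emissions[bi, :L], "path": path,
                        "probs": probs[bi, :L]})
        return out

    def predict(self, sentences: Sequence, batch_size: int = 32) -> list[LabeledSentence]:
        """Tag raw character sequences (or re-tag LabeledSentences)."""
        chars = [s.chars if isinstance(s, LabeledSentence) else list(s)
                 for s in sentences]
        results: list = [None] * len(chars)
        for batch in self.make_batches(chars, batch_size):
            for rec in self._decode_batch(batch):
                results[rec["index"]] = LabeledSentence(
                    chars=chars[rec["index"]], labels=rec["labels"])
        return results

    def predict_with_confidence(self, sentences: Sequence,
                                batch_size: int = 32) -> list[tuple]:
        """(LabeledSentence, confidence in [0,1]) per input sentence.

        Confidence = exp(mean per-token log-probability of the Viterbi path
        under the CRF) times the mean max type probability over predicted
        entity tokens (1.0 when no entity token is predicted).
        """
        chars = [s.chars if isinstance(s, LabeledSentence) else list(s)
                 for s in sentences]
        results: list = [None] * len(chars)
        for batch in self.make_batches(chars, batch_size):
            for rec in self._decode_batch(batch):
                L = len(rec["path"])
                lp = crf_path_log_prob(rec["emissions"], self.crf, rec["path"])
                crf_conf = float(np.exp(lp / max(L, 1)))
                ent_tok = [t for t, lab in enumerate(rec["labels"]) if lab != "O"]
                if ent_tok:
                    type_conf = float(np.mean([rec["probs"][t].max() for t in ent_tok]))
                else:
                    type_conf = 1.0
                sent = LabeledSentence(chars=chars[rec["index"]], labels=rec["labels"])
                results[rec["index"]] = (sent, crf_conf * type_conf)
        return results

    # -- evaluation ----------------------------------------------------------
    def evaluate(self, corpus: Sequence[LabeledSentence],
                 batch_size: int = 32) -> dict:
        """Entity-level P/R/F1 (exact span+type match) against gold labels."""
        pred = self.predict(corpus, batch_size)
        return entity_f1(list(corpus), pred)

    def type_accuracy(self, corpus: Sequence[LabeledSentence],
                      batch_size: int = 32) -> float:
        """Fraction of gold spans whose type the type branch resolves correctly.

        Gold boundaries are taken as given, isolating the type branch from
        boundary errors.
        """
        from .heads import resolve_span_type
        correct = total = 0
        for batch in self.make_batches([s for s in corpus], batch_size):
            recs = self._decode_batch(batch)
            for rec in recs:
                sent = corpus[rec["index"]]
                probs = rec["probs"]
                tok_types = [self.types[int(np.argmax(probs[t]))]
                             for t in range(len(sent))]
                for a, b, gold_type in extract_spans(sent.labels):
                    got = resolve_span_type(tok_types[a:b], (probs, self.types), a)
                    correct += int(got == gold_type)
                    total += 1
        return correct / total if total else 0.0

    # -- fitting (delegates to the training loop) ---------------------------
    def fit(self, train: Sequence[LabeledSentence],
            dev: Sequence[LabeledSentence] | None = None, train_config=None):
        from .training import train_supervised
        return train_supervised(self, train, dev, train_config)

    def fit_semisupervised(self, labeled, unlabeled, selftrain_config=None,
                           train_config=None, dev=None):
        from .training import self_train
        return self_train(self, labeled, unlabeled, selftrain_config,
                          train_config, dev)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: parameters (npz) + config/vocab sidecar (json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {
            "config": {**asdict(self.config),
                       "kernel_widths": list(self.config.kernel_widths)},
            "char_vocab": self.char2id,
            "types": self.types,
            "seed": self.seed,
            "dictionary": [[" ".join(s), t] for s, t in self.dictionary.entries],
            "radicals": self.radical_table.mapping,
            "unknown_radical": self.radical_table.unknown_radical,
        }
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path: str | Path) -> "DualBranchNER":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg_d = dict(meta["config"])
        cfg_d["kernel_widths"] = tuple(cfg_d["kernel_widths"])
        cfg = ModelConfig(**cfg_d)
        dictionary = EntityDictionary()
        for surface, etype in meta["dictionary"]:
            dictionary.add(tuple(surface.split(" ")), etype)
        table = RadicalTable(mapping=meta["radicals"],
                             unknown_radical=meta["unknown_radical"])
        model = cls(cfg, meta["char_vocab"], dictionary, table,
                    [t for t in meta["types"] if t != NONE_TYPE],
                    seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict(dict(data))
        return model
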