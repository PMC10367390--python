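"""Seeded synthetic corpora with the statistical structure the tagger exploits.

The generator emulates the regularities of clinical character text that the
model is built around, without any real data:

* a **gazetteer signal** — entities are planted verbatim from a generated
  entity dictionary, so maximum matching recovers them;
* a **radical signal** — each entity type has a characteristic radical that
  its characters carry with probability ``radical_strength`` (rho), the way
  disease characters share the "sickness" radical;
* **type ambiguity** — a configurable fraction of dictionary surfaces is
  drawn from a small *shared* character pool used by every type, so the
  surface's type cannot be read off its characters (or radicals) — the
  surfaces are mutually confusable strings over a handful of symbols — and
  is only recoverable through the dictionary-id context.  This is what
  makes the entity-dictionary ablation discriminative.

Characters and radicals are abstract symbols ("c017", "r3"); background
(non-entity) characters come from a sub-vocabulary disjoint from all
entity pools.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus_io import (EntityDictionary, LabeledSentence, RadicalTable,
                        write_bio_corpus, write_entity_dictionary,
                        write_radical_table, write_unlabeled_corpus)


@dataclass
class SynthConfig:
    vocab_size: int = 120            # total characters; ~40% entity pools, rest background
    radical_alphabet: int = 10       # first n_types radicals are type radicals
    n_types: int = 4
    dict_size: int = 40
    entity_len: tuple = (2, 4)       # inclusive surface-length range
    entities_per_sentence: float = 1.5   # Poisson mean
    sentence_len: tuple = (12, 30)   # inclusive length range
    radical_strength: float = 0.9    # rho: P(char carries its type's radical)
    ambiguity_rate: float = 0.3      # fraction of surfaces drawn from the shared pool
    shared_pool_size: int = 6        # characters in the type-ambiguous shared pool
    n_train: int = 500
    n_dev: int = 100
    n_test: int = 100
    n_unlabeled: int = 0
    seed: int = 0
    type_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.type_names:
            base = ["Dis", "Dru", "Sym", "Ana", "Che", "Sur", "Bod", "Dep"]
            self.type_names = [base[i] if i < len(base) else f"T{i}"
                               for i in range(self.n_types)]
        if self.entity_len[1] > self.sentence_len[0]:
            raise ValueError("entities longer than the shortest sentence are infeasible")
        if not 0.0 <= self.radical_strength <= 1.0:
            raise ValueError("radical_strength must be a probability")
        if self.radical_alphabet <= self.n_types:
            raise ValueError("need at least one generic radical beyond the type radicals")


@dataclass
class SynthDataset:
    train: list
    dev: list
    test: list
    unlabeled: list
    dictionary: EntityDictionary
    radical_table: RadicalTable
    manifest: dict
    config: SynthConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("train", "dev", "test"):
            write_bio_corpus(getattr(self, name), outdir / f"{name}.bio")
        write_unlabeled_corpus(self.unlabeled, outdir / "unlabeled.txt")
        write_entity_dictionary(self.dictionary, outdir / "dictionary.tsv")
        write_radical_table(self.radical_table, outdir / "radicals.tsv")
        payload = dict(self.manifest)
        payload["config"] = asdict(self.config)
        payload["config"]["entity_len"] = list(self.config.entity_len)
        payload["config"]["sentence_len"] = list(self.config.sentence_len)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _char_pools(cfg: SynthConfig) -> tuple[list[list[str]], list[str], list[str]]:
    """(per-type pools, shared ambiguous pool, background pool), all disjoint."""
    per_type = max(4, int(0.4 * cfg.vocab_size) // cfg.n_types)
    n_entity = per_type * cfg.n_types
    shared = cfg.shared_pool_size if cfg.ambiguity_rate > 0 else 0
    if n_entity + shared >= cfg.vocab_size:
        raise ValueError("vocab too small for the requested type pools")
    chars = [f"c{i:03d}" for i in range(cfg.vocab_size)]
    pools = [chars[t * per_type:(t + 1) * per_type] for t in range(cfg.n_types)]
    return pools, chars[n_entity:n_entity + shared], chars[n_entity + shared:]


def _radical_table(cfg: SynthConfig, pools, shared, background,
                   rng: np.random.Generator) -> RadicalTable:
    radicals = [f"r{i}" for i in range(cfg.radical_alphabet)]
    generic = radicals[cfg.n_types:]
    mapping = {}
    for t, pool in enumerate(pools):
        for ch in pool:
            if rng.random() < cfg.radical_strength:
                mapping[ch] = radicals[t]
            else:
                mapping[ch] = generic[rng.integers(len(generic))]
    for ch in list(shared) + list(background):
        mapping[ch] = generic[rng.integers(len(generic))]
    return RadicalTable(mapping=mapping)


def _build_dictionary(cfg: SynthConfig, pools, shared,
                      rng: np.random.Generator) -> tuple[EntityDictionary, list[bool]]:
    d = EntityDictionary()
    ambiguous_flags: list[bool] = []
    seen: set = set()
    lo, hi = cfg.entity_len
    for i in range(cfg.dict_size):
        t = i % cfg.n_types
        ambiguous = bool(shared) and rng.random() < cfg.ambiguity_rate
        pool = list(shared) if ambiguous else pools[t]
        for _attempt in range(200):
            L = int(rng.integers(lo, hi + 1))
            surface = tuple(pool[int(j)] for j in rng.integers(len(pool), size=L))
            if surface not in seen:
                break
        else:  # pragma: no cover - astronomically unlikely at default sizes
            raise RuntimeError("could not sample a fresh dictionary surface")
        seen.add(surface)
        d.add(surface, cfg.type_names[t])
        ambiguous_flags.append(ambiguous)
    return d, ambiguous_flags


def _make_sentence(cfg: SynthConfig, dictionary: EntityDictionary, background,
                   rng: np.random.Generator):
    T = int(rng.integers(cfg.sentence_len[0], cfg.sentence_len[1] + 1))
    n_ent = int(rng.poisson(cfg.entities_per_sentence))
    picks = []
    used = 0
    for _ in range(n_ent):
        eid = int(rng.integers(1, len(dictionary) + 1))
        L = len(dictionary.surface(eid))
        # interior gaps of >= 1 background char keep planted spans separated
        if used + L + len(picks) >= T:
            break
        picks.append(eid)
        used += L
    free = T - used
    n_gaps = len(picks) + 1
    # gap sizes: interior gaps >= 1, boundary gaps >= 0
    gaps = np.ones(n_gaps, dtype=int)
    gaps[0] = 0
    gaps[-1] = 0
    remaining = free - gaps.sum()
    if remaining > 0:
        extra = rng.multinomial(remaining, np.full(n_gaps, 1.0 / n_gaps))
        gaps = gaps + extra
    order = rng.permutation(len(picks))
    chars: list[str] = []
    labels: list[str] = []
    spans = []
    for gi, eidx in enumerate(order):
        for _ in range(int(gaps[gi])):
            chars.append(background[int(rng.integers(len(background)))])
            labels.append("O")
        eid = picks[eidx]
        surface = dictionary.surface(eid)
        etype = dictionary.type_of(eid)
        spans.append({"start": len(chars), "end": len(chars) + len(surface),
                      "type": etype, "dict_id": eid})
        for k, ch in enumerate(surface):
            chars.append(ch)
            labels.append(("B-" if k == 0 else "I-") + etype)
    for _ in range(int(gaps[len(picks)])):
        chars.append(background[int(rng.integers(len(background)))])
        labels.append("O")
    return LabeledSentence(chars=chars, labels=labels), spans


def generate(cfg: SynthConfig) -> SynthDataset:
    """Generate corpora, dictionary, radical table and a span manifest."""
    rng = np.random.default_rng(cfg.seed)
    pools, shared, background = _char_pools(cfg)
    table = _radical_table(cfg, pools, shared, background, rng)
    dictionary, ambiguous = _build_dictionary(cfg, pools, shared, rng)
    manifest: dict = {"spans": [], "ambiguous_entries": [i + 1 for i, a
                                                         in enumerate(ambiguous) if a]}
    splits = {}
    for split, n in (("train", cfg.n_train), ("dev", cfg.n_dev), ("test", cfg.n_test)):
        sentences = []
        for si in range(n):
            sent, spans = _make_sentence(cfg, dictionary, background, rng)
            for sp in spans:
                manifest["spans"].append({"split": split, "sentence": si, **sp})
            sentences.append(sent)
        splits[split] = sentences
    unlabeled = [_make_sentence(cfg, dictionary, background, rng)[0].chars
                 for _ in range(cfg.n_unlabeled)]
    return SynthDataset(train=splits["train"], dev=splits["dev"],
                        test=splits["test"], unlabeled=unlabeled,
                        dictionary=dictionary, radical_table=table,
                        manifest=manifest, config=cfg)


def degrade_labels(corpus, fraction: float, seed: int):
    """Seeded sentence-level split into (labeled subset, stripped remainder).

    The remainder is returned as bare character sequences, emulating an
    unlabeled pool drawn from the same distribution as the labeled data.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(corpus))
    n_lab = int(round(fraction * len(corpus)))
    labeled = [corpus[i] for i in sorted(idx[:n_lab])]
    unlabeled = [list(corpus[i].chars) for i in sorted(idx[n_lab:])]
    return labeled, unlabeled
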