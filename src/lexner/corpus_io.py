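"""Corpus, dictionary and radical-table I/O plus label-scheme utilities.

On-disk formats (all UTF-8 plain text):

* BIO corpus — one ``<token>\\t<tag>`` pair per line, blank line between
  sentences (CoNLL-2003 column dialect).  Tags are ``O`` or ``B-<type>`` /
  ``I-<type>``.
* Entity dictionary — ``<surface>\\t<type>`` per line.  A surface containing
  spaces is split on spaces into character tokens; otherwise it is split
  into unicode characters (so both abstract symbol vocabularies like
  ``c017 c042`` and CJK strings work).
* Radical table — ``<char>\\t<radical>`` per line.
* Unlabeled corpus — one sentence per line, tokens space-separated (or a
  bare string split into characters).

The full BIO-type tags decompose into the two branch targets the tagger
trains on: a boundary sequence over {B, I, O} and a per-token type sequence
(``NONE`` outside entities).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

NONE_TYPE = "NONE"


class CorpusFormatError(ValueError):
    """Malformed corpus / dictionary / radical file."""


@dataclass
class LabeledSentence:
    """A character sequence with BIO-type tags of equal length."""

    chars: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.chars) != len(self.labels):
            raise CorpusFormatError(
                f"chars ({len(self.chars)}) and labels ({len(self.labels)}) differ in length")

    def __len__(self) -> int:
        return len(self.chars)

    def entities(self) -> list[tuple[int, int, str]]:
        """Exact entity spans as (start, end_exclusive, type)."""
        return extract_spans(self.labels)


@dataclass
class BranchLabels:
    """Dual-branch supervision: boundary tags {B,I,O} and per-token types."""

    boundary: list[str]
    types: list[str]


@dataclass
class EntityDictionary:
    """Ordered gazetteer; ids are dense 1..N, 0 reserved for 'no match'."""

    entries: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def surface(self, idx: int) -> tuple[str, ...]:
        return self.entries[idx - 1][0]

    def type_of(self, idx: int) -> str:
        return self.entries[idx - 1][1]

    def add(self, surface: Sequence[str], etype: str) -> int:
        surface = tuple(surface)
        if not surface:
            raise CorpusFormatError("empty dictionary surface")
        for existing, _ in self.entries:
            if existing == surface:
                logger.warning("duplicate dictionary surface %r ignored", surface)
                return 0
        self.entries.append((surface, etype))
        return len(self.entries)

    @property
    def types(self) -> list[str]:
        return sorted({t for _, t in self.entries})


@dataclass
class RadicalTable:
    """char -> radical mapping, total after the unknown-radical fallback."""

    mapping: dict[str, str]
    unknown_radical: str = "<UNK_RAD>"

    def lookup(self, char: str) -> str:
        return self.mapping.get(char, self.unknown_radical)

    @property
    def radicals(self) -> list[str]:
        return sorted(set(self.mapping.values()) | {self.unknown_radical})


# ---------------------------------------------------------------------------
# BIO handling

def _split_tag(tag: str) -> tuple[str, str]:
    if tag == "O":
        return "O", NONE_TYPE
    if len(tag) > 2 and tag[1] == "-" and tag[0] in ("B", "I"):
        return tag[0], tag[2:]
    raise CorpusFormatError(f"unknown tag {tag!r}")


def repair_bio(labels: Sequence[str]) -> list[str]:
    """Promote orphan I-X (not preceded by B-X/I-X) to B-X."""
    out: list[str] = []
    prev_prefix, prev_type = "O", NONE_TYPE
    for tag in labels:
        prefix, etype = _split_tag(tag)
        if prefix == "I" and not (prev_prefix in ("B", "I") and prev_type == etype):
            prefix = "B"
        out.append("O" if prefix == "O" else f"{prefix}-{etype}")
        prev_prefix, prev_type = prefix, etype
    return out


def validate_bio(labels: Sequence[str]) -> None:
    prev_prefix, prev_type = "O", NONE_TYPE
    for i, tag in enumerate(labels):
        prefix, etype = _split_tag(tag)
        if prefix == "I" and not (prev_prefix in ("B", "I") and prev_type == etype):
            raise CorpusFormatError(f"orphan tag {tag!r} at position {i}")
        prev_prefix, prev_type = prefix, etype


def extract_spans(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """(start, end_exclusive, type) spans; orphan I starts a new span."""
    spans: list[tuple[int, int, str]] = []
    start, cur_type = None, None
    for i, tag in enumerate(labels):
        prefix, etype = _split_tag(tag)
        if prefix == "B" or (prefix == "I" and (start is None or etype != cur_type)):
            if start is not None:
                spans.append((start, i, cur_type))
            start, cur_type = i, etype
        elif prefix == "O":
            if start is not None:
                spans.append((start, i, cur_type))
            start, cur_type = None, None
    if start is not None:
        spans.append((start, len(labels), cur_type))
    return spans


def split_labels(sentence: LabeledSentence) -> BranchLabels:
    """Decompose BIO-type tags into boundary {B,I,O} and per-token types."""
    boundary, types = [], []
    for tag in sentence.labels:
        prefix, etype = _split_tag(tag)
        boundary.append(prefix)
        types.append(etype)
    return BranchLabels(boundary=boundary, types=types)


def merge_labels(branch: BranchLabels,
                 type_scores: "object | None" = None) -> list[str]:
    """Recombine boundary path and per-token types into BIO-type tags.

    For each maximal B..I span the span type is the majority vote of the
    per-token types, with ties (and all-NONE spans) resolved by mean type
    probability when ``type_scores`` is given (see
    :func:`lexner.heads.resolve_span_type`), else by lexicographic order.
    Orphan I tags in the boundary path open a new span.
    """
    from .heads import resolve_span_type  # deferred: avoids import cycle

    boundary = branch.boundary
    T = len(boundary)
    labels = ["O"] * T
    spans: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(boundary):
        if b == "B":
            if start is not None:
                spans.append((start, i))
            start = i
        elif b == "I":
            if start is None:
                start = i
        else:
            if start is not None:
                spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, T))
    for a, b in spans:
        etype = resolve_span_type(branch.types[a:b], type_scores, a)
        if etype == NONE_TYPE:
            continue  # unresolvable span (no votes, no scores) stays O
        labels[a] = f"B-{etype}"
        for i in range(a + 1, b):
            labels[i] = f"I-{etype}"
    return labels


# ---------------------------------------------------------------------------
# File I/O

def read_bio_corpus(path: str | Path, scheme: str = "strict") -> list[LabeledSentence]:
    """Read a CoNLL-style BIO file.

    ``scheme='repair'`` promotes orphan I-X to B-X; ``'strict'`` raises on
    invalid transitions.
    """
    if scheme not in ("strict", "repair"):
        raise ValueError(f"scheme must be 'strict' or 'repair', got {scheme!r}")
    sentences: list[LabeledSentence] = []
    chars: list[str] = []
    labels: list[str] = []

    def flush():
        if chars:
            labs = repair_bio(labels) if scheme == "repair" else list(labels)
            if scheme == "strict":
                validate_bio(labs)
            sentences.append(LabeledSentence(chars=list(chars), labels=labs))
            chars.clear()
            labels.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 2 tab-separated "
                                        f"columns, got {len(cols)}")
            _split_tag(cols[1])  # validate prefix early, with location
            chars.append(cols[0])
            labels.append(cols[1])
    flush()
    return sentences


def write_bio_corpus(sentences: Iterable[LabeledSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for ch, tag in zip(sent.chars, sent.labels):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def tokenize_surface(surface: str) -> tuple[str, ...]:
    """Split a surface string into character tokens (space-separated symbols
    if spaces are present, unicode characters otherwise)."""
    if " " in surface:
        return tuple(tok for tok in surface.split(" ") if tok)
    return tuple(surface)


def read_entity_dictionary(path: str | Path) -> EntityDictionary:
    d = EntityDictionary()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0].strip():
                raise CorpusFormatError(f"{path}:{lineno}: expected '<surface>\\t<type>'")
            d.add(tokenize_surface(cols[0]), cols[1])
    return d


def write_entity_dictionary(d: EntityDictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for surface, etype in d.entries:
            joined = " ".join(surface) if any(len(t) > 1 for t in surface) else "".join(surface)
            fh.write(f"{joined}\t{etype}\n")


def read_radical_table(path: str | Path) -> RadicalTable:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0].strip():
                raise CorpusFormatError(f"{path}:{lineno}: expected '<char>\\t<radical>'")
            mapping.setdefault(cols[0], cols[1])
    return RadicalTable(mapping=mapping)


def write_radical_table(table: RadicalTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ch, rad in table.mapping.items():
            fh.write(f"{ch}\t{rad}\n")


def read_unlabeled_corpus(path: str | Path) -> list[list[str]]:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sentences.append(list(tokenize_surface(line)))
    return sentences


def write_unlabeled_corpus(sentences: Iterable[Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chars in sentences:
            joined = " ".join(chars) if any(len(t) > 1 for t in chars) else "".join(chars)
            fh.write(joined + "\n")


# ---------------------------------------------------------------------------
# Entity-level metrics

def entity_f1(gold: Sequence[LabeledSentence],
              pred: Sequence[LabeledSentence]) -> dict:
    """Exact-match entity precision / recall / F1, per type and micro.

    A predicted span counts as a true positive iff (start, end, type) all
    match a gold span in the same sentence.  Zero denominators yield 0.
    """
    if len(gold) != len(pred):
        raise ValueError(f"corpus shapes differ: {len(gold)} vs {len(pred)} sentences")
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    for g, p in zip(gold, pred):
        if len(g) != len(p):
            raise ValueError("sentence lengths differ between gold and pred")
        gspans = set((a, b, t) for a, b, t in extract_spans(g.labels))
        pspans = set((a, b, t) for a, b, t in extract_spans(p.labels))
        for span in pspans & gspans:
            tp[span[2]] += 1
        for span in pspans - gspans:
            fp[span[2]] += 1
        for span in gspans - pspans:
            fn[span[2]] += 1

    def prf(t, f_p, f_n):
        p = t / (t + f_p) if t + f_p else 0.0
        r = t / (t + f_n) if t + f_n else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return {"precision": p, "recall": r, "f1": f}

    types = sorted(set(tp) | set(fp) | set(fn))
    report = {"per_type": {t: prf(tp[t], fp[t], fn[t]) for t in types}}
    report.update(prf(sum(tp.values()), sum(fp.values()), sum(fn.values())))
    return report
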