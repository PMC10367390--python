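"""Maximum entity matching against the gazetteer.

Each character position receives the integer id of the *longest* dictionary
surface that occurs in the sentence as a contiguous substring covering that
position; positions covered by no surface get 0.  The rule is per-position
(argmax over covering occurrences), not a left-to-right greedy segmentation.

Tie-break for equal-length covering occurrences: earliest start position,
then lowest dictionary id.
"""

from __future__ import annotations

from typing import Sequence

from .corpus_io import EntityDictionary


def find_occurrences(chars: Sequence[str],
                     dictionary: EntityDictionary) -> list[tuple[int, int, int]]:
    """All (start, length, id) occurrences of dictionary surfaces in ``chars``.

    Surfaces are grouped by first token so the scan is roughly
    O(T * surfaces-sharing-first-token); exact behaviour is fixed by the
    per-position oracle in the tests, not by this search strategy.
    """
    by_first: dict[str, list[tuple[tuple[str, ...], int]]] = {}
    for idx0, (surface, _t) in enumerate(dictionary.entries):
        by_first.setdefault(surface[0], []).append((surface, idx0 + 1))
    chars = tuple(chars)
    T = len(chars)
    occ: list[tuple[int, int, int]] = []
    for start in range(T):
        for surface, eid in by_first.get(chars[start], ()):
            L = len(surface)
            if start + L <= T and chars[start:start + L] == surface:
                occ.append((start, L, eid))
    return occ


def match_entities(chars: Sequence[str],
                   dictionary: EntityDictionary) -> list[int]:
    """Per-position id of the longest covering dictionary occurrence (0 = none)."""
    T = len(chars)
    # best[t] = (length, -start, -id) maximised lexicographically, i.e.
    # longest first, then earliest start, then lowest id.
    best: list[tuple[int, int, int] | None] = [None] * T
    for start, length, eid in find_occurrences(chars, dictionary):
        key = (length, -start, -eid)
        for t in range(start, start + length):
            if best[t] is None or key > best[t]:
                best[t] = key
    return [(-b[2]) if b is not None else 0 for b in best]
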