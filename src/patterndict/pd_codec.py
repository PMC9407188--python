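"""Greedy pattern-dictionary parser and the PDD codelength score.

A test sequence is covered left to right; each phrase is the longest prefix
of the remaining suffix that appears in the trained dictionary, capped at
depth ``Dmax``.  Because every prefix of a training pattern is itself a
training pattern, grow-until-failure and longest-prefix-match coincide, and
the greedy match is unique.  The total codelength is

    L(x) = sum_i L_D(phrase_i) + c * log2(Dmax)

(c phrases, one depth index each).  Either the codelength or the phrase
count serves as the PDD anomaly score: a window that parses into few, cheap
phrases looks like the training data; an anomalous one fragments.

A test symbol never seen in training is emitted as a single-symbol *escape*
phrase charged ``log2(a_1 + 1) + log2(alphabet)`` bits (escape index within
an enlarged depth-1 code plus a literal) on top of the depth index, keeping
the score finite on arbitrary inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dictionary import PatternDictionary

__all__ = ["ParseResult", "pd_parse", "pd_codelength", "pdd_score"]

_LEAF = 0  # trie slot: codelength at this node (None if not a pattern)
_KIDS = 1  # trie slot: children


@dataclass
class ParseResult:
    """Phrases covering a test sequence; 0-based half-open coordinates."""

    starts: list[int]  # start index of each phrase
    phrases: list[tuple[int, ...]]
    is_escape: list[bool]
    c: int  # phrase count
    codelength: float  # total bits, escapes included

    @property
    def escapes(self) -> int:
        return sum(self.is_escape)


def _parse_trie(pdict: PatternDictionary) -> dict:
    """Nested-dict trie over all patterns; node = [codelength, {symbol: node}]."""
    if pdict._parse_trie is None:
        root = [None, {}]
        for d in range(1, pdict.dmax + 1):
            for pat, entry in pdict.levels[d].items():
                node = root
                for s in pat[:-1]:
                    node = node[_KIDS][s]
                node = node[_KIDS].setdefault(pat[-1], [None, {}])
                node[_LEAF] = entry.codelength
        pdict._parse_trie = root
    return pdict._parse_trie


def pd_parse(pdict: PatternDictionary, test) -> ParseResult:
    """Greedy longest-match parse of ``test`` against a trained dictionary."""
    seq = tuple(int(s) for s in test)
    if not seq:
        raise ValueError("empty test sequence")
    if pdict.code_method is None:
        raise ValueError("dictionary has no codelengths; call assign_codelengths")
    root = _parse_trie(pdict)
    depth_bits = pdict.depth_index_bits
    a1 = len(pdict.levels[1])
    escape_bits = math.log2(a1 + 1) + math.log2(max(pdict.alphabet_size, 2))

    starts: list[int] = []
    phrases: list[tuple[int, ...]] = []
    escapes: list[bool] = []
    total = 0.0
    i, n = 0, len(seq)
    while i < n:
        node = root
        best_len = 0
        best_cl = 0.0
        j = i
        while j < n and j - i < pdict.dmax:
            child = node[_KIDS].get(seq[j])
            if child is None:
                break
            node = child
            j += 1
            if node[_LEAF] is not None:
                best_len = j - i
                best_cl = node[_LEAF]
        if best_len == 0:  # unseen symbol: escape literal
            starts.append(i)
            phrases.append((seq[i],))
            escapes.append(True)
            total += depth_bits + escape_bits
            i += 1
        else:
            starts.append(i)
            phrases.append(seq[i : i + best_len])
            escapes.append(False)
            total += depth_bits + best_cl
            i += best_len
    return ParseResult(
        starts=starts,
        phrases=phrases,
        is_escape=escapes,
        c=len(phrases),
        codelength=total,
    )


def pd_codelength(pdict: PatternDictionary, parse: ParseResult) -> float:
    """Recompute the total codelength of a parse (consistency entry point)."""
    depth_bits = pdict.depth_index_bits
    a1 = len(pdict.levels[1])
    escape_bits = math.log2(a1 + 1) + math.log2(max(pdict.alphabet_size, 2))
    total = 0.0
    for phrase, esc in zip(parse.phrases, parse.is_escape):
        if esc:
            total += depth_bits + escape_bits
        else:
            total += depth_bits + pdict.codelength_of(phrase)
    return total


def pdd_score(pdict: PatternDictionary, test, statistic: str = "codelength") -> float:
    """PDD anomaly score of a window: total codelength or phrase count."""
    if statistic not in ("codelength", "phrases"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    parse = pd_parse(pdict, test)
    return parse.codelength if statistic == "codelength" else float(parse.c)
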