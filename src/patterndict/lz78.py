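"""Incremental (tree-structured) Lempel–Ziv parsing and its codelength.

LZ78 parses a sequence into phrases, each one a previously seen phrase
extended by a single symbol (the first phrase being a bare symbol).  All
phrases are distinct except possibly the last, which may end mid-extension.
Following the codelength convention used throughout this package, a parse
into ``c`` phrases costs

    L_A = c * log2(c + 1)   bits

(the per-phrase cost of naming one of the ``c`` earlier phrases, including
the empty root).  The classical variant that also charges the innovation
symbol, ``c * (log2 c + log2 X)``, is available behind a flag.  LZ78 serves
as the *atypical* (universal) coder in the atypicality score, against the
trained pattern dictionary as the typical coder.

Also provided: ``log_star``, the iterated-logarithm cost
``log2 l + log2 log2 l + ...`` over the strictly positive terms, used as the
universal penalty for an unknown window length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["LZParse", "lz78_parse", "lz78_codelength", "log_star"]


@dataclass
class LZParse:
    phrases: list[tuple[int, ...]]
    c: int
    codelength: float


def lz78_parse(seq) -> LZParse:
    """Standard LZ78 incremental parse over a trie; counts the final
    (possibly duplicate) phrase."""
    s = tuple(int(x) for x in seq)
    if not s:
        raise ValueError("empty sequence")
    trie: dict[tuple[int, int], int] = {}  # (node_id, symbol) -> node_id
    next_id = 1  # 0 is the root
    phrases: list[tuple[int, ...]] = []
    node = 0
    start = 0
    for i, sym in enumerate(s):
        child = trie.get((node, sym))
        if child is None:
            trie[(node, sym)] = next_id
            next_id += 1
            phrases.append(s[start : i + 1])
            node = 0
            start = i + 1
        else:
            node = child
    if start < len(s):  # tail phrase that never left the trie
        phrases.append(s[start:])
    c = len(phrases)
    return LZParse(phrases=phrases, c=c, codelength=c * math.log2(c + 1))


def lz78_codelength(seq, *, classical: bool = False, alphabet_size: int | None = None) -> float:
    """Codelength of the LZ78 parse: ``c log2(c+1)``, or the classical
    ``c (log2 c + log2 X)`` when ``classical`` is set."""
    parse = lz78_parse(seq)
    c = parse.c
    if not classical:
        return parse.codelength
    if alphabet_size is None:
        alphabet_size = max(int(x) for x in seq) + 1
    return c * (math.log2(max(c, 1)) + math.log2(max(alphabet_size, 2)))


def log_star(l: int) -> float:
    """Iterated-log sum ``log2 l + log2 log2 l + ...`` over positive terms."""
    if l < 1:
        raise ValueError("l must be >= 1")
    total = 0.0
    x = float(l)
    while True:
        x = math.log2(x)
        if x <= 0:
            break
        total += x
    return total
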