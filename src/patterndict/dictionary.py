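"""Multi-level pattern dictionary: construction, probabilities, codelengths.

A pattern dictionary over a training sequence of length ``L`` collects, for
every depth ``d = 1..Dmax``, the set ``S^d`` of all distinct length-``d``
subsequences together with their occurrence counts.  The empirical
probability of a depth-``d`` pattern is ``count / (L - d + 1)`` (the number
of length-``d`` windows), and each level is given its own optimal prefix
code (Huffman by default, Shannon–Fano–Elias optionally), so the full index
of a pattern costs ``log2(Dmax) + L^d(pattern)`` bits: a depth index plus a
within-level codeword.

Splitting the patterns by depth (a multi-level dictionary) always yields an
average indexing codelength no larger than a single flat index over all
patterns; the gap is exactly ``log2(A/G)`` where ``A`` and ``G`` are the
arithmetic and geometric means of the per-level sizes.  See
:func:`indexing_codelength_gap`.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternEntry",
    "PatternDictionary",
    "build_dictionary",
    "assign_codelengths",
    "indexing_codelength",
    "indexing_codelength_gap",
    "UnknownPatternError",
]

Pattern = tuple[int, ...]


class UnknownPatternError(KeyError):
    """Raised when a pattern is not present in the dictionary."""


@dataclass
class PatternEntry:
    count: int
    prob: float
    codelength: float | None = None  # bits; None until codes are assigned


@dataclass
class PatternDictionary:
    """Per-depth tables of patterns with counts, probabilities, codelengths.

    ``levels[d]`` maps each depth-``d`` pattern (a tuple of symbols) to its
    :class:`PatternEntry`; depths run 1..Dmax inclusive.
    """

    dmax: int
    alphabet_size: int
    train_length: int
    levels: dict[int, dict[Pattern, PatternEntry]]
    code_method: str | None = None
    integer_depth_index: bool = False
    _parse_trie: dict | None = field(default=None, repr=False, compare=False)

    @property
    def level_sizes(self) -> list[int]:
        return [len(self.levels[d]) for d in range(1, self.dmax + 1)]

    @property
    def depth_index_bits(self) -> float:
        """Cost in bits of encoding the depth of a phrase."""
        b = math.log2(self.dmax) if self.dmax > 1 else 0.0
        return math.ceil(b) if self.integer_depth_index else b

    def __contains__(self, pattern) -> bool:
        p = tuple(int(s) for s in pattern)
        lvl = self.levels.get(len(p))
        return lvl is not None and p in lvl

    def codelength_of(self, pattern) -> float:
        p = tuple(int(s) for s in pattern)
        lvl = self.levels.get(len(p))
        if lvl is None or p not in lvl:
            raise UnknownPatternError(p)
        cl = lvl[p].codelength
        if cl is None:
            raise ValueError("codelengths not assigned; call assign_codelengths")
        return cl

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "Dmax": self.dmax,
            "alphabet_size": self.alphabet_size,
            "L": self.train_length,
            "code_method": self.code_method,
            "integer_depth_index": self.integer_depth_index,
            "levels": [
                {
                    "d": d,
                    "entries": [
                        {
                            "pattern": list(p),
                            "count": e.count,
                            "prob": e.prob,
                            "codelength": e.codelength,
                        }
                        for p, e in sorted(self.levels[d].items())
                    ],
                }
                for d in range(1, self.dmax + 1)
            ],
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatternDictionary":
        obj = json.loads(text)
        levels: dict[int, dict[Pattern, PatternEntry]] = {}
        for lvl in obj["levels"]:
            levels[int(lvl["d"])] = {
                tuple(e["pattern"]): PatternEntry(
                    count=int(e["count"]),
                    prob=float(e["prob"]),
                    codelength=e["codelength"],
                )
                for e in lvl["entries"]
            }
        return cls(
            dmax=int(obj["Dmax"]),
            alphabet_size=int(obj["alphabet_size"]),
            train_length=int(obj["L"]),
            levels=levels,
            code_method=obj.get("code_method"),
            integer_depth_index=bool(obj.get("integer_depth_index", False)),
        )


def build_dictionary(train, dmax: int, alphabet_size: int | None = None) -> PatternDictionary:
    """Collect all distinct patterns of depth 1..dmax from a training sequence.

    ``train`` is any iterable of integer symbols; its length ``L`` must
    exceed ``dmax``.  Probabilities use the window count ``L - d + 1`` as
    denominator.  Codelengths are left unassigned.
    """
    seq = tuple(int(s) for s in train)
    L = len(seq)
    if L == 0:
        raise ValueError("empty training sequence")
    if dmax < 1:
        raise ValueError("dmax must be >= 1")
    if dmax >= L:
        raise ValueError(f"dmax ({dmax}) must be smaller than the training length ({L})")
    if alphabet_size is None:
        alphabet_size = max(seq) + 1
    levels: dict[int, dict[Pattern, PatternEntry]] = {}
    for d in range(1, dmax + 1):
        counts: dict[Pattern, int] = {}
        for i in range(L - d + 1):
            key = seq[i : i + d]
            counts[key] = counts.get(key, 0) + 1
        denom = L - d + 1
        levels[d] = {p: PatternEntry(c, c / denom) for p, c in counts.items()}
    return PatternDictionary(
        dmax=dmax, alphabet_size=alphabet_size, train_length=L, levels=levels
    )


# -- prefix-code assignment ----------------------------------------------


def _huffman_codelengths(items: list[tuple[Pattern, int]]) -> dict[Pattern, int]:
    """Optimal prefix codelengths for one level, reproducible tie-break.

    Equal-weight leaves are merged in reverse-lexicographic pattern order;
    merged nodes rank after all equal-weight leaves, in creation order.
    A single-item level gets codelength 1 (a zero-length word is not a
    usable prefix code).
    """
    if len(items) == 1:
        return {items[0][0]: 1}
    # leaves keyed so the lexicographically largest pattern pops first
    order = {p: r for r, (p, _) in enumerate(sorted(items))}
    heap: list[tuple[int, int, list]] = []
    for p, w in items:
        # node = [list of (pattern, depth)] accumulated
        heapq.heappush(heap, (w, -order[p] - len(items), [[p, 0]]))
    created = 0
    while len(heap) > 1:
        w1, _, n1 = heapq.heappop(heap)
        w2, _, n2 = heapq.heappop(heap)
        for leaf in n1:
            leaf[1] += 1
        for leaf in n2:
            leaf[1] += 1
        heapq.heappush(heap, (w1 + w2, created, n1 + n2))
        created += 1
    _, _, leaves = heap[0]
    return {p: depth for p, depth in leaves}


def assign_codelengths(pdict: PatternDictionary, method: str = "huffman") -> PatternDictionary:
    """Assign per-level prefix codelengths in place (and return the dict).

    ``huffman`` gives optimal integer codelengths per level; ``sfe``
    (Shannon–Fano–Elias) gives ``ceil(log2(1/p)) + 1``.  Either way a level
    holding a single pattern costs 1 bit.
    """
    if method not in ("huffman", "sfe"):
        raise ValueError(f"unknown code method: {method!r}")
    for d in range(1, pdict.dmax + 1):
        lvl = pdict.levels[d]
        if not lvl:
            continue
        if any(e.prob <= 0 for e in lvl.values()):
            raise ValueError(f"zero probability at depth {d}")
        if method == "huffman":
            lengths = _huffman_codelengths([(p, e.count) for p, e in lvl.items()])
            for p, e in lvl.items():
                e.codelength = float(lengths[p])
        else:
            for p, e in lvl.items():
                if len(lvl) == 1:
                    e.codelength = 1.0
                else:
                    e.codelength = float(math.ceil(math.log2(1.0 / e.prob)) + 1)
    pdict.code_method = method
    pdict._parse_trie = None
    return pdict


def indexing_codelength(pdict: PatternDictionary, pattern) -> float:
    """Full multi-level index cost of one pattern: depth index + codeword."""
    return pdict.depth_index_bits + pdict.codelength_of(pattern)


# -- uni-level vs multi-level indexing ------------------------------------


def indexing_codelength_gap(level_sizes) -> dict[str, float]:
    """Compare flat (uni-level) and depth-split (multi-level) indexing.

    For per-level pattern counts ``a_1..a_Dmax`` returns::

        L_uni   = log2(sum a_d)                      (flat index)
        L_multi = log2(Dmax) + mean_d log2(a_d)      (depth + within-level)
        gap     = L_uni - L_multi = log2(A/G) >= 0

    with ``A``/``G`` the arithmetic/geometric means of the ``a_d``.  The
    returned ``gap_lower_bound``/``gap_upper_bound`` are advisory analytic
    bounds built from endpoint (min/max) AM−GM gap inequalities: the lower
    uses ``(sqrt(a_max)-sqrt(a_min))²/Dmax <= A−G`` with denominator
    ``a_max >= G``, the upper uses the endpoint-concentration bound
    ``A−G <= w·a_min + (1−w)·a_max − LM`` (``LM`` the logarithmic mean of
    the endpoints, ``w = ln(a_max/LM)/ln(a_max/a_min)``) with denominator
    ``a_min <= G``.
    """
    a = np.asarray(list(level_sizes), dtype=float)
    if a.size == 0:
        raise ValueError("empty level-size vector")
    if np.any(a < 1):
        raise ValueError("every level size must be >= 1")
    n = a.size
    l_uni = math.log2(a.sum())
    l_multi = math.log2(n) + float(np.mean(np.log2(a)))
    amin, amax = float(a.min()), float(a.max())
    if amin == amax:
        gap = 0.0
        lo = hi = 0.0
    else:
        gap = l_uni - l_multi
        ag_lower = (math.sqrt(amax) - math.sqrt(amin)) ** 2 / n
        lm = (amax - amin) / math.log(amax / amin)
        w = math.log(amax / lm) / math.log(amax / amin)
        ag_upper = w * amin + (1 - w) * amax - (amin**w) * (amax ** (1 - w))
        lo = math.log2(1.0 + ag_lower / amax)
        hi = math.log2(1.0 + ag_upper / amin)
    return {
        "L_uni": l_uni,
        "L_multi": l_multi,
        "gap": gap,
        "gap_lower_bound": lo,
        "gap_upper_bound": hi,
    }
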