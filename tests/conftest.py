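"""Shared fixtures: the worked-example dictionary, independent reference
parsers (oracles), and one session-scoped run of the Mackey–Glass
benchmark reused by the evaluation and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from patterndict.dictionary import assign_codelengths, build_dictionary
from patterndict.evaluation import run_benchmark

EXAMPLE_STRING = "ABACADABBACCADDABABACADAB"


def letters(s: str) -> list[int]:
    return [ord(c) - 65 for c in s]


def pattern(s: str) -> tuple[int, ...]:
    return tuple(ord(c) - 65 for c in s)


@pytest.fixture(scope="session")
def example_seq() -> list[int]:
    return letters(EXAMPLE_STRING)


@pytest.fixture(scope="session")
def table1_dict(example_seq):
    """Depth-3 Huffman-coded dictionary of the 25-symbol worked example."""
    return assign_codelengths(build_dictionary(example_seq, 3))


# -- independent oracles --------------------------------------------------


def lz78_oracle(seq) -> list[tuple[int, ...]]:
    """Set-based LZ78 reference: grow the current phrase until it is new."""
    seen: set[tuple[int, ...]] = set()
    phrases: list[tuple[int, ...]] = []
    cur: tuple[int, ...] = ()
    for s in seq:
        cur += (int(s),)
        if cur not in seen:
            seen.add(cur)
            phrases.append(cur)
            cur = ()
    if cur:
        phrases.append(cur)
    return phrases


def pd_parse_oracle(pdict, seq) -> list[tuple[int, ...]]:
    """Exhaustive longest-prefix reference for the dictionary parser."""
    s = tuple(int(x) for x in seq)
    phrases: list[tuple[int, ...]] = []
    i = 0
    while i < len(s):
        best = 0
        for d in range(1, min(pdict.dmax, len(s) - i) + 1):
            if s[i : i + d] in pdict:
                best = d
        if best == 0:
            phrases.append(s[i : i + 1])
            i += 1
        else:
            phrases.append(s[i : i + best])
            i += best
    return phrases


def lambertw_bisect(x: float, tol: float = 1e-14) -> float:
    """Principal-branch Lambert W by bisection on w*exp(w) = x, x >= 0."""
    if x < 0:
        raise ValueError("principal branch oracle defined for x >= 0 only")
    lo, hi = 0.0, 1.0
    while hi * np.exp(hi) < x:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * np.exp(mid) < x:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# -- the shared benchmark run ---------------------------------------------


@pytest.fixture(scope="session")
def mg_benchmark():
    """20-replicate, high-resolution benchmark over all six detectors."""
    return run_benchmark(
        ("pda", "pdd", "zm", "nns", "cdm", "tstide"),
        n_replicates=20,
        resolution="high",
        dmax=40,
        window=100,
        seed=0,
    )
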