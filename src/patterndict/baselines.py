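"""Reference anomaly detectors for the sliding-window benchmark.

Four classical sequence scores, each computed for a test window against a
training sequence:

- **ZM** (Ziv–Merhav cross-parsing): number of phrases when the window is
  sequentially covered by the longest substrings occurring anywhere in the
  training data; few long matches = similar sequences.
- **NNS**: distance from the window to its nearest equal-length training
  subsequence.
- **CDM**: compression-based dissimilarity, compressed size of the
  concatenation over the sum of separately compressed sizes (about 1 for
  unrelated sequences, below 1 for related ones).
- **t-STIDE**: one minus the average training frequency of the window's
  length-``l`` sub-windows.
"""

from __future__ import annotations

import bz2
import zlib
from collections import Counter

import numpy as np

__all__ = [
    "zm_score",
    "nns_score",
    "cdm_score",
    "tstide_score",
    "tstide_sweep",
    "train_window_index",
    "subwindow_frequencies",
]


def _to_str(seq) -> str:
    return "".join(chr(int(s)) for s in seq)


def zm_score(train, window, mode: str = "onfly") -> int:
    """Cross-parse the window against all substrings of the training data.

    Greedy: from each position take the longest prefix of the remaining
    window that occurs somewhere in ``train`` (a symbol absent from the
    training data consumes one position).  Returns the phrase count.
    ``codebook`` precomputes the substring set; ``onfly`` searches the
    training string directly.  Both give identical scores.
    """
    t = _to_str(train)
    w = _to_str(window)
    if not t:
        raise ValueError("empty training sequence")
    if not w:
        raise ValueError("empty window")
    if mode not in ("onfly", "codebook"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "codebook":
        book = train_window_index(train, len(w))
        c = 0
        i = 0
        while i < len(w):
            j = i + 1
            while j <= len(w) and w[i:j] in book:
                j += 1
            # w[i:j-1] matched (or nothing: consume one symbol)
            i = max(j - 1, i + 1)
            c += 1
        return c
    c = 0
    i = 0
    n = len(w)
    while i < n:
        # binary search the longest match length (monotone in length)
        lo, hi = 0, n - i  # lo = known matchable length
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if w[i : i + mid] in t:
                lo = mid
            else:
                hi = mid - 1
        i += max(lo, 1)
        c += 1
    return c


def train_window_index(train, max_len: int) -> set[str]:
    """Set of all training substrings up to ``max_len`` (ZM codebook)."""
    t = _to_str(train)
    book: set[str] = set()
    for d in range(1, max_len + 1):
        for i in range(len(t) - d + 1):
            book.add(t[i : i + d])
    return book


def nns_score(train, window, metric: str = "euclidean") -> float:
    """Distance from the window to the nearest equal-length training
    subsequence (all alignments)."""
    t = np.asarray(train, dtype=float)
    w = np.asarray(window, dtype=float)
    if w.size > t.size:
        raise ValueError("window longer than the training sequence")
    views = np.lib.stride_tricks.sliding_window_view(t, w.size)
    if metric == "euclidean":
        # |v - w|^2 = |v|^2 - 2 v.w + |w|^2, via BLAS
        d2 = (views**2).sum(axis=1) - 2.0 * views @ w + w @ w
        return float(np.sqrt(max(d2.min(), 0.0)))
    if metric == "hamming":
        return float((views != w).sum(axis=1).min())
    raise ValueError(f"unknown metric: {metric!r}")


_COMPRESSORS = {
    "zlib": lambda b: len(zlib.compress(b, 9)),
    "bz2": lambda b: len(bz2.compress(b, 9)),
}


def cdm_score(train, window, compressor: str = "zlib") -> float:
    """Compression-based dissimilarity of the window and the training data:
    ``L(train + window) / (L(train) + L(window))``."""
    if compressor not in _COMPRESSORS:
        raise ValueError(f"unknown compressor: {compressor!r}")
    size = _COMPRESSORS[compressor]
    tb = _seq_bytes(train)
    wb = _seq_bytes(window)
    return size(tb + wb) / (size(tb) + size(wb))


def _seq_bytes(seq) -> bytes:
    arr = np.asarray(seq)
    if arr.size and arr.max() > 255:
        return arr.astype("<u2").tobytes()
    return arr.astype(np.uint8).tobytes()


def subwindow_frequencies(train, l: int) -> tuple[Counter, int]:
    """Counts of all length-``l`` training subsequences and their number."""
    t = tuple(int(s) for s in train)
    n = len(t) - l + 1
    if n < 1:
        raise ValueError("training sequence shorter than l")
    return Counter(t[i : i + l] for i in range(n)), n


def tstide_score(train, window, l: int, _index=None) -> float:
    """One minus the mean normalized training frequency of the window's
    length-``l`` sub-windows."""
    w = tuple(int(s) for s in window)
    if not 1 <= l <= len(w):
        raise ValueError("l out of range")
    counts, n = subwindow_frequencies(train, l) if _index is None else _index
    likes = [counts.get(w[i : i + l], 0) / n for i in range(len(w) - l + 1)]
    return 1.0 - float(np.mean(likes))


def tstide_sweep(train, windows, labels, ls, auc_fn) -> dict[int, float]:
    """Helper: ROC AUC of t-STIDE for each candidate sub-window length."""
    out = {}
    for l in ls:
        index = subwindow_frequencies(train, l)
        scores = [tstide_score(train, w, l, _index=index) for w in windows]
        out[l] = auc_fn(scores, labels)
    return out
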