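"""Atypicality scoring: typical (pattern-dictionary) minus atypical (LZ78)
codelength, the variable-length scanner, and threshold calibration.

A window is *atypical* if a universal coder describes it in fewer bits than
the coder trained on typical data.  The score of a window ``x`` is

    PDA(x) = L_T(x) - L_A(x)

with ``L_T`` the pattern-dictionary codelength (phrase codewords plus depth
indices) and ``L_A = c log2(c+1)`` the LZ78 codelength.  When scanning for
anomalous subsequences of unknown length, ``L_A`` additionally carries the
universal integer cost ``log*(l)`` for describing the window length, and a
start position is flagged when the best window length exceeds the
threshold:  ``max_l [L_T - L_A - log*(l)] > tau``.

``tau`` can be calibrated from the training data alone: hold out contiguous
folds, score each fold's windows against a dictionary built on the
remainder, and take an upper quantile of the pooled null scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import assign_codelengths, build_dictionary, PatternDictionary
from .lz78 import log_star, lz78_parse
from .pd_codec import pd_parse

__all__ = ["ScoreTrack", "pda_score", "scan", "calibrate_tau"]


@dataclass
class ScoreTrack:
    """Per-window anomaly scores; windows are 0-based half-open."""

    windows: list[tuple[int, int]]
    scores: np.ndarray
    tau: float | None = None
    labels: np.ndarray | None = None

    def flagged(self, tau: float | None = None) -> np.ndarray:
        """Boolean flag per window: score strictly above threshold."""
        t = self.tau if tau is None else tau
        if t is None:
            raise ValueError("no threshold given")
        return self.scores > t

    def sample_mask(self, n_samples: int, tau: float | None = None) -> np.ndarray:
        """Per-sample anomaly mask: union of flagged windows."""
        mask = np.zeros(n_samples, dtype=bool)
        for (s, e), f in zip(self.windows, self.flagged(tau)):
            if f:
                mask[s:e] = True
        return mask


def pda_score(pdict: PatternDictionary, window, *, include_penalty: bool = False) -> float:
    """Typical-minus-atypical codelength of one window (bits).

    With ``include_penalty`` the LZ78 side carries the ``log*`` cost of the
    window length (needed when the length is not fixed in advance; a pure
    constant for fixed-window experiments, so off by default).
    """
    seq = np.asarray(window)
    if seq.size == 0:
        raise ValueError("empty window")
    l_t = pd_parse(pdict, seq).codelength
    l_a = lz78_parse(seq).codelength
    if include_penalty:
        l_a += log_star(len(seq))
    return l_t - l_a


def scan(pdict: PatternDictionary, seq, lengths, tau: float) -> ScoreTrack:
    """Variable-length anomaly scan over every start position.

    For each start ``n`` the score is the maximum over candidate window
    lengths of ``L_T - L_A - log*(l)``; the recorded window is the
    maximizing one.  Positions where no candidate length fits are skipped.
    """
    s = np.asarray(seq)
    lens = sorted(set(int(l) for l in lengths))
    if not lens:
        raise ValueError("empty length set")
    if lens[0] < 1:
        raise ValueError("window lengths must be >= 1")
    if lens[-1] > s.size:
        raise ValueError("largest window length exceeds the sequence")
    penalties = {l: log_star(l) for l in lens}
    windows: list[tuple[int, int]] = []
    scores: list[float] = []
    for n in range(s.size - lens[0] + 1):
        best = -np.inf
        best_l = None
        for l in lens:
            if n + l > s.size:
                break
            val = pda_score(pdict, s[n : n + l]) - penalties[l]
            if val > best:
                best, best_l = val, l
        if best_l is not None:
            windows.append((n, n + best_l))
            scores.append(best)
    return ScoreTrack(windows=windows, scores=np.asarray(scores), tau=tau)


def calibrate_tau(
    train,
    dmax: int,
    folds: int = 30,
    quantile: float = 0.99,
    *,
    window_length: int | None = None,
    stride: int | None = None,
    code_method: str = "huffman",
    include_penalty: bool = False,
) -> float:
    """Cross-validated null quantile of the PDA score on typical data.

    The training sequence is split into ``folds`` contiguous blocks; each
    block is scored (sliding windows of ``window_length``, default the
    block length, advancing by ``stride``, default the window length)
    against a dictionary built on the remaining blocks.  Returns the
    requested empirical quantile of the pooled scores.
    """
    seq = np.asarray(train)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    edges = np.linspace(0, seq.size, folds + 1).astype(int)
    fold_len = int(np.diff(edges).min())
    wlen = fold_len if window_length is None else int(window_length)
    if wlen < 1 or wlen > fold_len:
        raise ValueError(
            f"window length {wlen} does not fit in a fold of {fold_len} samples"
        )
    step = wlen if stride is None else int(stride)
    pooled: list[float] = []
    for i in range(folds):
        held = seq[edges[i] : edges[i + 1]]
        rest = np.concatenate([seq[: edges[i]], seq[edges[i + 1] :]])
        pdict = assign_codelengths(build_dictionary(rest, dmax), code_method)
        for s in range(0, held.size - wlen + 1, step):
            pooled.append(
                pda_score(pdict, held[s : s + wlen], include_penalty=include_penalty)
            )
    return float(np.quantile(pooled, quantile))
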