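"""Benchmark evaluation: window labels, ROC/PR AUC, sensitivity, and the
sliding-window Mackey–Glass comparison of all detectors.

The benchmark trains every detector on one quantized MG series (3000
samples, typical source), slides a length-100 window over replicate test
sequences (1500 samples, a 500-sample anomalous segment grafted at
position 500), scores every window, and summarizes per-replicate ROC and
precision–recall AUCs as mean +/- sd per method.  A window counts as
anomalous when at least half of it overlaps the grafted segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import baselines
from .atypicality import pda_score
from .dictionary import assign_codelengths, build_dictionary
from .pd_codec import pdd_score
from .quantize import encode, fit_quantizer
from .simulate import benchmark_train_params, mackey_glass, make_benchmark_testset

__all__ = [
    "window_labels",
    "roc_pr_auc",
    "sensitivity",
    "BenchmarkResult",
    "run_benchmark",
    "RESOLUTIONS",
]

RESOLUTIONS = {"high": 90, "medium": 45, "low": 10}


def window_labels(sample_labels, windows, overlap_threshold: float = 0.5) -> np.ndarray:
    """Label each window 1 iff its anomalous-sample overlap fraction
    reaches ``overlap_threshold``."""
    lab = np.asarray(sample_labels).astype(bool)
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap threshold must be in (0, 1]")
    cum = np.concatenate([[0], np.cumsum(lab)])
    out = np.empty(len(windows), dtype=int)
    for k, (s, e) in enumerate(windows):
        if not (0 <= s < e <= lab.size):
            raise ValueError(f"window ({s}, {e}) out of range")
        out[k] = 1 if (cum[e] - cum[s]) / (e - s) >= overlap_threshold else 0
    return out


def roc_pr_auc(scores, labels) -> tuple[float, float]:
    """ROC AUC (rank statistic) and PR AUC (step-wise interpolation)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to compute AUCs")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def sensitivity(flagged_samples, sample_labels) -> float:
    """True positive rate on samples: TP / (TP + FN)."""
    f = np.asarray(flagged_samples).astype(bool)
    y = np.asarray(sample_labels).astype(bool)
    if f.size != y.size:
        raise ValueError("length mismatch")
    pos = int(y.sum())
    if pos == 0:
        raise ValueError("no positive samples")
    return float((f & y).sum() / pos)


@dataclass
class BenchmarkResult:
    method: str
    roc_aucs: list[float] = field(default_factory=list)
    pr_aucs: list[float] = field(default_factory=list)

    @property
    def roc_mean(self) -> float:
        return float(np.mean(self.roc_aucs))

    @property
    def roc_sd(self) -> float:
        return float(np.std(self.roc_aucs, ddof=1))

    @property
    def pr_mean(self) -> float:
        return float(np.mean(self.pr_aucs))

    @property
    def pr_sd(self) -> float:
        return float(np.std(self.pr_aucs, ddof=1))


def run_benchmark(
    methods=("pda", "pdd", "zm", "nns", "cdm", "tstide"),
    *,
    n_replicates: int = 20,
    resolution: str = "high",
    dmax: int = 40,
    window: int = 100,
    seed: int = 0,
    train_len: int = 3000,
    tstide_l: int = 6,
) -> dict[str, BenchmarkResult]:
    """Run the sliding-window MG anomaly benchmark.

    One typical training series is generated and quantized (uniform
    quantizer, ``RESOLUTIONS[resolution]`` levels); each replicate test
    series gets fresh host/segment initializations.  Seeds for the
    replicate sources are derived from ``seed``.
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution: {resolution!r}")
    alphabet = RESOLUTIONS[resolution]
    base = int(seed) * 1_000_003 % (2**31)

    train_series = mackey_glass(train_len, benchmark_train_params(seed=base))
    model = fit_quantizer(train_series, n_levels=alphabet)
    train = encode(model, train_series)

    needs_dict = {"pda", "pdd"} & set(methods)
    pdict = None
    if needs_dict:
        pdict = assign_codelengths(build_dictionary(train, dmax, alphabet_size=alphabet))
    tstide_index = (
        baselines.subwindow_frequencies(train, tstide_l) if "tstide" in methods else None
    )

    results = {m: BenchmarkResult(m) for m in methods}
    for rep in range(n_replicates):
        series, labels = make_benchmark_testset(base + 17 * (rep + 1))
        test = encode(model, series)
        starts = range(len(test) - window + 1)
        wins = [(s_, s_ + window) for s_ in starts]
        ylab = window_labels(labels, wins)
        for m in methods:
            scores = _score_windows(m, train, pdict, test, wins, tstide_l, tstide_index)
            roc, pr = roc_pr_auc(scores, ylab)
            results[m].roc_aucs.append(roc)
            results[m].pr_aucs.append(pr)
    return results


def _score_windows(method, train, pdict, test, wins, tstide_l, tstide_index):
    out = np.empty(len(wins))
    for k, (s, e) in enumerate(wins):
        w = test[s:e]
        if method == "pda":
            out[k] = pda_score(pdict, w)
        elif method == "pdd":
            out[k] = pdd_score(pdict, w)
        elif method == "zm":
            out[k] = baselines.zm_score(train, w)
        elif method == "nns":
            out[k] = baselines.nns_score(train, w)
        elif method == "cdm":
            out[k] = baselines.cdm_score(train, w)
        elif method == "tstide":
            out[k] = baselines.tstide_score(train, w, tstide_l, _index=tstide_index)
        else:
            raise ValueError(f"unknown method: {method!r}")
    return out
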