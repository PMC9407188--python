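"""Uniform quantization of real-valued time series into discrete symbol sequences.

All coders in this package operate on sequences over a finite alphabet
``{0, ..., K-1}``.  Real-valued (possibly multichannel) signals are first
discretized per channel by a uniform quantizer, and the per-channel bin
indices are combined into a single symbol by a row-major product code, so a
D-channel signal becomes a one-dimensional symbol stream over an alphabet of
size ``prod(n_levels)``.

Bins are half-open ``[min + k*step, min + (k+1)*step)``; the top edge of the
fitted range maps to the last bin, and out-of-range test values clamp to the
nearest edge bin so that any test signal remains codable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np

__all__ = [
    "QuantizerModel",
    "fit_quantizer",
    "encode",
    "downsample_mean",
    "mad_outlier_mask",
]


@dataclass(frozen=True)
class QuantizerModel:
    """Per-channel uniform quantizer plus the product-code alphabet.

    Attributes
    ----------
    mins : tuple of float
        Observed per-channel minima of the fitting data (signal units).
    steps : tuple of float
        Per-channel bin widths (signal units, positive).
    n_levels : tuple of int
        Per-channel bin counts (each >= 1).
    """

    mins: tuple[float, ...]
    steps: tuple[float, ...]
    n_levels: tuple[int, ...]

    @property
    def n_channels(self) -> int:
        return len(self.mins)

    @property
    def alphabet_size(self) -> int:
        return int(np.prod(self.n_levels))

    def to_json(self) -> str:
        return json.dumps(
            {
                "mins": list(self.mins),
                "steps": list(self.steps),
                "n_levels": list(self.n_levels),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantizerModel":
        d = json.loads(text)
        return cls(
            mins=tuple(float(v) for v in d["mins"]),
            steps=tuple(float(v) for v in d["steps"]),
            n_levels=tuple(int(v) for v in d["n_levels"]),
        )


def _as_matrix(series) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("series must be 1-D or 2-D (time x channels)")
    return arr


def fit_quantizer(
    series,
    *,
    steps: TypingSequence[float] | float | None = None,
    n_levels: TypingSequence[int] | int | None = None,
) -> QuantizerModel:
    """Fit a per-channel uniform quantizer to a T x D signal matrix.

    Exactly one of ``steps`` (per-channel bin width) or ``n_levels``
    (per-channel bin count) must be given; scalars broadcast to all channels.
    With ``steps`` the level count is ``ceil((max-min)/step)`` (at least 1);
    with ``n_levels`` the step is ``(max-min)/n_levels`` (a degenerate
    constant channel gets a single bin).
    """
    arr = _as_matrix(series)
    t, d = arr.shape
    if t < 2:
        raise ValueError("need at least 2 time points to fit a quantizer")
    for ch in range(d):
        if not np.all(np.isfinite(arr[:, ch])):
            raise ValueError(f"non-finite values in channel {ch}")
    if (steps is None) == (n_levels is None):
        raise ValueError("give exactly one of steps= or n_levels=")

    mins = arr.min(axis=0)
    maxs = arr.max(axis=0)
    out_steps: list[float] = []
    out_levels: list[int] = []
    if steps is not None:
        step_arr = np.broadcast_to(np.atleast_1d(np.asarray(steps, float)), (d,))
        for ch in range(d):
            step = float(step_arr[ch])
            if step <= 0:
                raise ValueError(f"non-positive step for channel {ch}")
            span = maxs[ch] - mins[ch]
            levels = max(1, int(np.ceil(span / step)))
            out_steps.append(step)
            out_levels.append(levels)
    else:
        lev_arr = np.broadcast_to(np.atleast_1d(np.asarray(n_levels, int)), (d,))
        for ch in range(d):
            levels = int(lev_arr[ch])
            if levels < 1:
                raise ValueError(f"level count < 1 for channel {ch}")
            span = maxs[ch] - mins[ch]
            if span == 0.0:
                levels, step = 1, 1.0
            else:
                step = span / levels
            out_steps.append(float(step))
            out_levels.append(levels)
    return QuantizerModel(
        mins=tuple(float(m) for m in mins),
        steps=tuple(out_steps),
        n_levels=tuple(out_levels),
    )


def encode(model: QuantizerModel, series) -> np.ndarray:
    """Quantize a T x D signal into a length-T symbol sequence.

    Per channel: ``bin = floor((x - min)/step)`` clamped to
    ``[0, n_levels-1]``; channels combine row-major, i.e. the symbol is
    ``sum_d bin_d * stride_d`` with the last channel varying fastest.
    """
    arr = _as_matrix(series)
    if arr.shape[1] != model.n_channels:
        raise ValueError(
            f"channel-count mismatch: model has {model.n_channels}, "
            f"series has {arr.shape[1]}"
        )
    mins = np.asarray(model.mins)
    steps = np.asarray(model.steps)
    levels = np.asarray(model.n_levels)
    bins = np.floor((arr - mins) / steps).astype(np.int64)
    bins = np.clip(bins, 0, levels - 1)
    strides = np.concatenate([np.cumprod(levels[::-1])[-2::-1], [1]]).astype(np.int64)
    return (bins * strides).sum(axis=1)


def downsample_mean(series, window: int) -> np.ndarray:
    """Downsample by averaging non-overlapping blocks of ``window`` samples.

    A trailing partial block is averaged as-is.  Used to reduce wearable
    streams to e.g. one sample per minute before quantization.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = _as_matrix(series)
    t = arr.shape[0]
    edges = np.arange(0, t, window)
    out = np.stack([arr[s : s + window].mean(axis=0) for s in edges])
    return out[:, 0] if np.asarray(series).ndim == 1 else out


def mad_outlier_mask(series, threshold: float = 5.0) -> np.ndarray:
    """Flag technical-noise outliers per channel by the MAD rule.

    Returns a boolean mask (True = keep) marking samples whose deviation
    from the channel median exceeds ``threshold`` robust standard deviations
    (MAD scaled by 1.4826) in any channel.  A simple stand-in for sensor
    dropout removal; constant channels flag nothing.
    """
    arr = _as_matrix(series)
    med = np.median(arr, axis=0)
    mad = np.median(np.abs(arr - med), axis=0) * 1.4826
    mad = np.where(mad == 0, np.inf, mad)
    keep = np.all(np.abs(arr - med) <= threshold * mad, axis=1)
    return keep
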