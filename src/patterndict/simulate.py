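"""Synthetic benchmark signals: Mackey–Glass series and i.i.d. sequences.

The Mackey–Glass delay differential equation

    dx/dt = -a x(t) + b x(t - delta) / (1 + x(t - delta)^10)

was introduced as a model of physiological control loops and is a standard
chaotic benchmark signal.  The integrator implements the equation exactly
as written above; note that the chaotic regime of the classic benchmark has
the *small* coefficient on the decay term (decay 0.1, delayed drive 0.2,
delta = 17).  With the roles reversed (decay 0.2, drive 0.1) the only fixed
point is 0 and the trajectory dies out, so the benchmark constructors below
use the classic role assignment; :class:`MGParams` lets callers pick either.

Integration is fixed-step 4th-order Runge–Kutta with linear interpolation
of the delayed state (dt = 0.1 by default), constant history 1.2, a
1000-time-unit burn-in, and one output sample per time unit.  A seed adds a
tiny jitter to the history so replicates decorrelate through the chaos.

The anomaly benchmark grafts a normalized segment from an anomalous MG
source into the middle of a typical MG host series, yielding a labeled test
sequence (e.g. 500 anomalous samples inside 1000 typical ones -> length
1500 with positions [500, 1000) anomalous).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MGParams",
    "mackey_glass",
    "graft_anomaly",
    "iid_sequence",
    "benchmark_train_params",
    "benchmark_anomaly_params",
    "make_benchmark_testset",
]


@dataclass(frozen=True)
class MGParams:
    a: float = 0.1  # coefficient on the instantaneous (decay) term
    b: float = 0.2  # coefficient on the delayed drive
    delta: float = 17.0  # delay, time units
    dt: float = 0.1  # integration step
    sample_every: float = 1.0  # output one sample per this many time units
    burn_in: float = 1000.0  # discarded lead-in, time units
    history_value: float = 1.2
    seed: int | None = None  # jitters the history; None = exact constant

    def __post_init__(self):
        if self.a <= 0 or self.b < 0 or self.delta <= 0 or self.dt <= 0:
            raise ValueError("a, delta, dt must be positive; b nonnegative")
        if self.dt >= self.delta:
            raise ValueError("dt must be smaller than the delay")


def benchmark_train_params(seed: int | None = None) -> MGParams:
    """Typical-source parameters of the anomaly benchmark (chaotic)."""
    return MGParams(a=0.1, b=0.2, delta=17.0, seed=seed)


def benchmark_anomaly_params(seed: int | None = None) -> MGParams:
    """Anomalous-source parameters: both coefficients doubled."""
    return MGParams(a=0.2, b=0.4, delta=17.0, seed=seed)


def mackey_glass(n: int, params: MGParams = MGParams()) -> np.ndarray:
    """Integrate the MG equation and return ``n`` post-burn-in samples."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params
    dt = p.dt
    lag_steps = p.delta / dt
    total_time = p.burn_in + n * p.sample_every
    n_steps = int(round(total_time / dt)) + 1
    hist_len = int(np.ceil(lag_steps)) + 2

    x = np.empty(hist_len + n_steps)
    if p.seed is None:
        x[:hist_len] = p.history_value
    else:
        rng = np.random.default_rng(p.seed)
        x[:hist_len] = p.history_value + 1e-3 * rng.standard_normal(hist_len)

    a, b = p.a, p.b

    def delayed(idx_float: float) -> float:
        lo = int(np.floor(idx_float))
        frac = idx_float - lo
        return x[lo] * (1.0 - frac) + x[lo + 1] * frac

    def f(xt: float, xd: float) -> float:
        return -a * xt + b * xd / (1.0 + xd**10)

    # RK4; delayed state at t, t+dt/2, t+dt via grid interpolation
    for i in range(hist_len - 1, hist_len + n_steps - 1):
        xd0 = delayed(i - lag_steps)
        xdh = delayed(i + 0.5 - lag_steps)
        xd1 = delayed(i + 1.0 - lag_steps)
        xi = x[i]
        k1 = f(xi, xd0)
        k2 = f(xi + 0.5 * dt * k1, xdh)
        k3 = f(xi + 0.5 * dt * k2, xdh)
        k4 = f(xi + dt * k3, xd1)
        x[i + 1] = xi + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    stride = int(round(p.sample_every / dt))
    first = hist_len - 1 + int(round(p.burn_in / dt)) + stride
    idx = first + stride * np.arange(n)
    return x[idx].copy()


def graft_anomaly(normal, anomalous, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Insert a normalized anomalous segment into a host series.

    The segment is affinely rescaled to the host's mean and standard
    deviation, then inserted at ``start``; returns the spliced series
    (length host + segment) and 0/1 labels marking the grafted positions.
    """
    host = np.asarray(normal, dtype=float)
    seg = np.asarray(anomalous, dtype=float)
    if not 0 <= start <= len(host):
        raise ValueError("start outside the host series")
    hm, hs = host.mean(), host.std()
    sm, ss = seg.mean(), seg.std()
    scaled = hm + (seg - sm) * (hs / ss if ss > 0 else 0.0)
    out = np.concatenate([host[:start], scaled, host[start:]])
    labels = np.zeros(len(out), dtype=int)
    labels[start : start + len(seg)] = 1
    return out, labels


def make_benchmark_testset(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One replicate of the benchmark test layout: a 500-sample anomalous
    MG segment inside 1000 typical MG samples -> (series of length 1500,
    labels on [500, 1000))."""
    host = mackey_glass(1000, benchmark_train_params(seed=2 * seed + 1))
    seg = mackey_glass(500, benchmark_anomaly_params(seed=2 * seed + 2))
    return graft_anomaly(host, seg, start=500)


def iid_sequence(
    alphabet_size: int,
    probs,
    l: int,
    *,
    exact_type: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Draw an i.i.d. symbol sequence; with ``exact_type`` the empirical
    symbol counts are forced to ``round(l * p_k)`` (adjusted to sum to l)
    and the multiset is shuffled."""
    p = np.asarray(probs, dtype=float)
    if p.size != alphabet_size or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a length-alphabet_size distribution")
    rng = np.random.default_rng(seed)
    if not exact_type:
        return rng.choice(alphabet_size, size=l, p=p)
    counts = np.floor(l * p).astype(int)
    rem = l - counts.sum()
    order = np.argsort(-(l * p - counts))  # largest fractional parts first
    counts[order[:rem]] += 1
    seq = np.repeat(np.arange(alphabet_size), counts)
    rng.shuffle(seq)
    return seq
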