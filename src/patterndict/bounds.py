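"""Non-asymptotic phrase-count bounds for LZ78 and the atypicality score range.

For an X-ary sequence of length ``l`` the number of distinct LZ78 phrases
``c(l)`` satisfies

    (sqrt(8l+1) - 1)/2  <=  c(l)  <=  l ln X / W((beta/alpha) X^{-(alpha+1)/alpha} ln X)

with ``alpha = X - 1``, ``beta = (X-1)^2 l - X`` and ``W`` the principal
branch of the Lambert W function.  The lower bound comes from a single
repeating symbol (phrases of lengths 1, 2, 3, ...); the upper from packing
all strings of length <= k, whose total length l_k inverts through W.  At
``l = l_k`` the upper bound equals ``l_k / (k - 1/alpha)`` exactly.

A looser closed form (no W) is ``c(l) <= l / ((1-eps_l) log_X l)`` with
``eps_l -> 0``; and restricting to a source of entropy ``h`` bits/symbol,
replacing the alphabet by the typical-set growth rate ``m = 2^{h+eps}``
gives a distribution-dependent bound depending on the source only through
its entropy.

Combining the pattern-dictionary parser range ``l/Dmax <= c_T <= l`` with
the LZ78 range yields the attainable range of the phrase-count difference
``c_T - c_A``, the backbone of the atypicality anomaly score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import lambertw

__all__ = [
    "BoundReport",
    "lz78_lower_bound",
    "lz78_upper_bound",
    "lz78_log_upper_bound",
    "typical_set_upper_bound",
    "pda_score_range",
    "max_phrase_construction_length",
]


@dataclass(frozen=True)
class BoundReport:
    l: int
    alphabet_size: int
    lower: float
    upper: float
    w_argument: float
    alpha: float
    beta: float
    k: float


def lz78_lower_bound(l: int) -> float:
    """Minimal LZ78 phrase count of any length-``l`` sequence:
    ``(sqrt(8l+1)-1)/2``, attained by a constant sequence at triangular l."""
    if l < 1:
        raise ValueError("l must be >= 1")
    return (math.sqrt(8.0 * l + 1.0) - 1.0) / 2.0


def _w_upper(l: float, m: float) -> tuple[float, float, float, float]:
    """Shared W inversion: returns (upper bound, W argument, alpha, beta)."""
    alpha = m - 1.0
    beta = (m - 1.0) ** 2 * l - m
    if beta <= 0:
        raise ValueError(f"l={l} too small for alphabet/growth rate {m} (W argument <= 0)")
    arg = (beta / alpha) * m ** (-(alpha + 1.0) / alpha) * math.log(m)
    w = float(lambertw(arg).real)
    return l * math.log(m) / w, arg, alpha, beta


def lz78_upper_bound(l: int, alphabet_size: int) -> float:
    """Maximal LZ78 phrase count of any X-ary length-``l`` sequence,
    expressed through the principal-branch Lambert W function."""
    if alphabet_size < 2:
        raise ValueError("alphabet size must be >= 2")
    if l < 1:
        raise ValueError("l must be >= 1")
    bound, _, _, _ = _w_upper(float(l), float(alphabet_size))
    return bound


def bound_report(l: int, alphabet_size: int) -> BoundReport:
    """Lower/upper phrase-count bounds plus the W-inversion internals."""
    bound, arg, alpha, beta = _w_upper(float(l), float(alphabet_size))
    w = float(lambertw(arg).real)
    k = w / math.log(alphabet_size) + 1.0 / alpha
    return BoundReport(
        l=l,
        alphabet_size=alphabet_size,
        lower=lz78_lower_bound(l),
        upper=bound,
        w_argument=arg,
        alpha=alpha,
        beta=beta,
        k=k,
    )


def lz78_log_upper_bound(l: int, alphabet_size: int) -> float:
    """W-free bound ``l / ((1-eps_l) log_X l)``;  +inf when ``eps_l = 1``.

    ``eps_l = min(1, (log log l - log(X-1) + (3X-2)/(X-1)) / log l)`` with
    all logs base X.
    """
    if l < 2:
        raise ValueError("l must be >= 2")
    x = alphabet_size
    if x < 2:
        raise ValueError("alphabet size must be >= 2")
    logx = lambda v: math.log(v) / math.log(x)
    ll = logx(l)
    eps = min(1.0, (logx(ll) - logx(x - 1) + (3 * x - 2) / (x - 1)) / ll)
    if eps >= 1.0:
        return math.inf
    return l / ((1.0 - eps) * ll)


def typical_set_upper_bound(l: int, entropy_h: float, eps: float) -> float:
    """Distribution-dependent phrase-count bound through the entropy only.

    The typical set of depth ``n`` holds at most ``2^{n(h+eps)}`` strings;
    substituting the continuous growth rate ``m = 2^{h+eps}`` for the
    alphabet size in the packing argument gives
    ``c(l, p) <= m (m^k - 1)/(m - 1)`` with ``k`` from the same W inversion.
    """
    if entropy_h <= 0 or eps <= 0:
        raise ValueError("entropy and eps must be positive")
    m = 2.0 ** (entropy_h + eps)
    _, arg, alpha, _ = _w_upper(float(l), m)
    w = float(lambertw(arg).real)
    k = w / math.log(m) + 1.0 / alpha
    return m * (m**k - 1.0) / (m - 1.0)


def pda_score_range(l: int, alphabet_size: int, dmax: int) -> tuple[float, float]:
    """Attainable range of ``c_T - c_A`` (dictionary phrases minus LZ78
    phrases) for an escape-free length-``l`` window."""
    if dmax < 1 or l <= dmax:
        raise ValueError("need l > dmax >= 1")
    low = l / dmax - lz78_upper_bound(l, alphabet_size)
    high = l - lz78_lower_bound(l)
    return low, high


def max_phrase_construction_length(k: int, alphabet_size: int) -> int:
    """``l_k``: total length of all distinct strings of length <= k, the
    sequence lengths at which the LZ78 upper bound is tight."""
    m = alphabet_size
    return sum(j * m**j for j in range(1, k + 1))
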