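"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid numpy quantile/statistics routines and the scipy /
statsmodels tests that the implementation itself relies on: medians and
quantiles are computed from sorted lists, the signed-rank null by explicit
enumeration of all sign assignments, and McNemar's exact p from the
binomial closed form.
"""

from __future__ import annotations

import math


def median_oracle(values) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def quantile_oracle(values, q: float) -> float:
    """Linear interpolation of order statistics: position h = (n-1)q."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def iqr_oracle(values) -> float:
    return quantile_oracle(values, 0.75) - quantile_oracle(values, 0.25)


def p30_oracle(mgfr, egfr) -> float:
    hits = sum(1 for m, e in zip(mgfr, egfr) if abs(e - m) <= 0.30 * m)
    return hits / len(mgfr)


def _abs_ranks(z) -> list[float]:
    order = sorted(range(len(z)), key=lambda i: abs(z[i]))
    ranks = [0.0] * len(z)
    for rank, i in enumerate(order, start=1):
        ranks[i] = float(rank)
    return ranks


def wilcoxon_enumeration_p(z) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    (no ties or zeros assumed; n <= ~16)."""
    n = len(z)
    ranks = _abs_ranks(z)
    w_obs = sum(r for zi, r in zip(z, ranks) if zi > 0)
    le = ge = 0
    for pattern in range(2**n):
        w = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        le += w <= w_obs
        ge += w >= w_obs
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


def mcnemar_exact_p(b: int, c: int) -> float:
    """Two-sided exact McNemar p: 2 * P(Binom(b+c, 1/2) <= min(b, c))."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, j) for j in range(k + 1)) * 0.5**n
    return min(1.0, 2.0 * tail)
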