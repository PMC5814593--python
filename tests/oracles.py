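"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and libraries) they validate:
exact rational hypergeometric enumeration for the two-sided Fisher test,
the textbook step-up formula for Benjamini-Hochberg, and hypergeometric
survival by direct summation for one-sided enrichment.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs), Fraction(0))
    return float(total)


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def hypergeom_sf_at_least(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)
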