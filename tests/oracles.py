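"""Independent brute-force oracles used to check the statistical core.

Everything here is computed from first principles (exact rational
arithmetic, literal definitions) and never calls into vea's own code paths
for the quantity under test.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

# tables within this relative factor of the observed point probability are
# counted into the two-sided tail (the R/scipy tie convention)
_REL_TOL = Fraction(10**7 + 1, 10**7)


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact Fraction arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    denom = comb(n, col1)

    def point(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)

    obs = point(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    total = sum(point(x) for x in range(lo, hi + 1) if point(x) <= obs * _REL_TOL)
    return float(min(Fraction(1), total))


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample OR with the Haldane-Anscombe +0.5 rule on any zero cell."""
    if 0 in (a, b, c, d):
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def bh_stepup(p_values: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up definition, O(m^2):
    adjusted_i = min over j with p_j >= p_i of m*p_j/rank_j, capped at 1,
    where rank_j is the 1-based position of p_j in ascending order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    rank = {}
    for pos, idx in enumerate(order, start=1):
        rank[idx] = pos
    adjusted = []
    for i in range(m):
        candidates = [
            m * p_values[j] / rank[j] for j in range(m) if p_values[j] >= p_values[i]
        ]
        adjusted.append(min(1.0, min(candidates)))
    return adjusted


def hypergeom_upper_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M population, K successes, N draws),
    by exact enumeration."""
    if k <= 0:
        return 1.0
    denom = comb(M, N)
    total = sum(
        Fraction(comb(K, x) * comb(M - K, N - x), denom)
        for x in range(k, min(K, N) + 1)
        if N - x <= M - K
    )
    return float(min(Fraction(1), total))
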