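"""Independent brute-force oracles used by the test suite.

Exact rational-arithmetic enumeration for hypergeometric / Fisher tails and
closed forms for binomial sampling noise — deliberately separate from the
scipy/statsmodels code paths they check.
"""

from fractions import Fraction
from math import comb


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    lo = max(k, 0)
    hi = min(K, n)
    s = sum(comb(K, j) * comb(N - K, n - j) for j in range(lo, hi + 1))
    return Fraction(s, total)


def fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (enrichment) Fisher p for the 2x2 table [[a, b], [c, d]].

    Enumerates all tables with the same margins and at least ``a`` in the
    top-left cell.
    """
    N = a + b + c + d
    return hypergeom_upper_tail(a, N, a + b, a + c)


def binomial_penetrance_rel_sd(p: float, n: int) -> float:
    """Closed-form relative SD of a penetrance estimate from n Bernoulli cells."""
    return (float((1 - p) / (n * p))) ** 0.5


def percentile_linear(sorted_vals, q: float) -> float:
    """Linear-interpolation percentile on a pre-sorted sample (independent
    of numpy): rank = q/100 * (n-1), interpolate between order statistics."""
    n = len(sorted_vals)
    rank = q / 100.0 * (n - 1)
    lo = int(rank)
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac
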