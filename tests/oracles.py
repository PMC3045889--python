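"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: exact rational
arithmetic for the digital-expression test, and full subset enumeration for
the resampling enrichment analysis.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact-rational two-sided Audic-Claverie p-value.

    Sums the conditional law p(k|x) = r^k (x+k)!/(x! k! (1+r)^(x+k+1)),
    r = N2/N1, term by term with ``fractions.Fraction``; the two-sided p
    doubles the smaller of the inclusive lower tail and the strict upper
    tail, capped at 1.
    """
    r = Fraction(n2, n1)
    # pmf(0|x) = 1/(1+r)^(x+1); pmf(k+1) = pmf(k) * r * (x+k+1) / ((k+1)(1+r))
    pmf = Fraction(1, 1) / (1 + r) ** (x + 1)
    lower = pmf
    for k in range(y):
        pmf = pmf * r * (x + k + 1) / ((k + 1) * (1 + r))
        lower += pmf
    upper_strict = 1 - lower
    return min(Fraction(1), 2 * min(lower, upper_strict))


def gsr_exact_tail(scores: dict[str, float], members: list[str]) -> float:
    """Exact tail probability of a category's mean score under resampling.

    Enumerates every size-k subset of the scored universe and returns the
    fraction whose mean is at least the observed category mean (the
    observed subset itself is always counted, so the tail is never zero).
    """
    k = len(members)
    observed = sum(scores[a] for a in members) / k
    universe = sorted(scores)
    total = comb(len(universe), k)
    hits = 0
    for subset in combinations(universe, k):
        if sum(scores[a] for a in subset) / k >= observed - 1e-12:
            hits += 1
    return hits / total
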