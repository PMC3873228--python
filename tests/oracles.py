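"""Independent brute-force oracles used by the test suite.

These are deliberately naive: exact rational arithmetic and direct
application of textbook definitions, written before and independently of
the library code paths they check.
"""

from fractions import Fraction
from math import comb


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by enumerating all tables with the margins.

    Point-probability rule, exact rational arithmetic: sum the central
    hypergeometric probabilities of every table no more probable than
    the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return total


def bh_definitional(pvalues, q):
    """BH step-up exactly as defined: find the largest i with p_(i) <= i*q/m,
    reject hypotheses ranked 1..i. Returns (flags in input order, threshold)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    kstar = 0
    for rank, idx in enumerate(indexed, start=1):
        if pvalues[idx] <= rank * q / m:
            kstar = rank
    flags = [False] * m
    for idx in indexed[:kstar]:
        flags[idx] = True
    threshold = pvalues[indexed[kstar - 1]] if kstar else 0.0
    return flags, threshold


def km_no_censoring(event_times):
    """Empirical survival function S(t) = #(T > t)/n at each event time."""
    n = len(event_times)
    times = sorted(set(event_times))
    return {t: sum(1 for x in event_times if x > t) / n for t in times}
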