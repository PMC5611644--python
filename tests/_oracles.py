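"""Independent brute-force oracles used only by the test suite.

Everything here works in exact rational arithmetic (fractions.Fraction)
by direct enumeration, deliberately sharing no code with the package's
implementations.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating every table with the same margins.

    Sums the exact point probabilities of all tables whose probability
    does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    n, k = r1 + r2, a + c
    if r1 == 0 or r2 == 0:
        return Fraction(1)
    denom = comb(n, k)
    pmf = {
        i: Fraction(comb(r1, i) * comb(r2, k - i), denom)
        for i in range(max(0, k - r2), min(r1, k) + 1)
    }
    obs = pmf[a]
    return min(Fraction(1), sum(p for p in pmf.values() if p <= obs))


def bh_stepup_selection(p: np.ndarray, alpha: float) -> np.ndarray:
    """Classical Benjamini-Hochberg step-up: boolean selection mask.

    Finds the largest k with p_(k) <= k*alpha/m and rejects the k
    smallest p-values.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) * alpha) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def bh_adjusted_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up adjusted values q_(i) = min_{j>=i} m*p_(j)/j, input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    raw = m * sorted_p / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_tail_oracle(
    n_universe: int, n_set1: int, n_set2: int, k: int, upper: bool
) -> Fraction:
    """Exact hypergeometric tail P(X >= k) or P(X <= k) by enumeration."""
    denom = comb(n_universe, n_set2)
    lo = max(0, n_set1 + n_set2 - n_universe)
    hi = min(n_set1, n_set2)
    support = range(k, hi + 1) if upper else range(lo, k + 1)
    total = sum(
        comb(n_set1, i) * comb(n_universe - n_set1, n_set2 - i) for i in support
    )
    return Fraction(total, denom)
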