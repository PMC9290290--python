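"""Independent brute-force oracles for the exact tests.

These enumerate entire discrete outcome spaces directly from first
principles (factorial hypergeometric / binomial point masses) and are kept
free of the implementation paths they check.
"""
from math import comb

import numpy as np

_REL_TOL = 1e-9


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= obs * (1 + _REL_TOL):
            total += p
    return min(total, 1.0)


def binom_two_sided_enum(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided binomial p by enumerating all n + 1 outcomes."""
    pmf = np.array([comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)])
    obs = pmf[k]
    return float(min(pmf[pmf <= obs * (1 + _REL_TOL)].sum(), 1.0))


def hypergeom_upper_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    denom = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x) / denom
        for x in range(k, min(K, n) + 1)
    )
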