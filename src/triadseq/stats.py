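"""Exact tests and multiple-testing procedures shared by every analysis stage.

Two-sided p-values use the probability-ordering convention: the p-value is
the total probability of all outcomes whose point probability does not exceed
that of the observed outcome.  For the 2x2 Fisher test this is the definition
scipy implements; it differs from doubling the smaller tail.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError

FdrMethod = Literal["bh", "by"]


@dataclass
class PValueVector:
    """Raw and FDR-adjusted p-values for a family of tests."""

    ids: np.ndarray
    p: np.ndarray
    q: np.ndarray
    method: str

    def __len__(self) -> int:
        return len(self.p)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def fisher_exact_counts(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    All tables with the observed margins whose hypergeometric probability is
    at most that of the observed table contribute to the p-value.  An all-zero
    table carries no information and returns p = 1 with a warning.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValidationError("Fisher table cells must be non-negative")
    if sum(cells) == 0:
        warnings.warn("all-zero 2x2 table; p set to 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_vector(
    k1: Sequence[int], rest1: Sequence[int], k2: Sequence[int], rest2: Sequence[int]
) -> np.ndarray:
    """Row-wise two-sided Fisher p for tables [[k1, rest1], [k2, rest2]]."""
    k1 = np.asarray(k1, dtype=np.int64)
    rest1 = np.asarray(rest1, dtype=np.int64)
    k2 = np.asarray(k2, dtype=np.int64)
    rest2 = np.asarray(rest2, dtype=np.int64)
    out = np.ones(len(k1))
    for i in range(len(k1)):
        if k1[i] + rest1[i] + k2[i] + rest2[i] == 0:
            continue  # uninformative row; p stays 1
        out[i] = sps.fisher_exact(
            [[k1[i], rest1[i]], [k2[i], rest2[i]]], alternative="two-sided"
        )[1]
    return out


def binom_two_sided(k: int, n: int, p0: float = 0.5, midp: bool = False) -> float:
    """Exact two-sided binomial p-value for k successes out of n vs rate p0.

    With ``midp`` the point probability of outcomes exactly as likely as the
    observed one contributes only half its mass (mid-p correction), which
    trades exactness for reduced conservatism on discrete counts.
    """
    if not 0 <= k <= n or n < 1:
        raise ValidationError("need 0 <= k <= n and n >= 1")
    if midp:
        pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
        obs = pmf[k]
        tol = 1e-12 * obs if obs > 0 else 0.0
        return float(pmf[pmf < obs - tol].sum() + 0.5 * pmf[np.abs(pmf - obs) <= tol].sum())
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def adjust_fdr(
    p: Sequence[float],
    method: FdrMethod = "bh",
    ids: Sequence | None = None,
) -> PValueVector:
    """Benjamini-Hochberg (bh) or Benjamini-Yekutieli (by) step-up adjustment.

    BH: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1.  BY multiplies by the
    harmonic factor c(n) = sum_{k<=n} 1/k, which is valid under arbitrary
    dependence between the tests.
    """
    p = np.asarray(p, dtype=float)
    ids = np.asarray(ids if ids is not None else np.arange(len(p)))
    if np.isnan(p).any():
        bad = list(ids[np.isnan(p)])
        raise ValidationError(f"NaN p-values for ids {bad[:10]}")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("bh", "by"):
        raise ValidationError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    if len(p) == 0:
        return PValueVector(ids, p, p.copy(), method)
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    q = multipletests(p, method=sm_method)[1]
    return PValueVector(ids, p, np.minimum(q, 1.0), method)


def welch_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample t test from summary statistics.

    Welch's unequal-variance form with Welch-Satterthwaite degrees of freedom
    by default; ``equal_var`` switches to the Student pooled-variance test.
    Two degenerate zero-variance groups compare by their means alone.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.inf) * np.sign(mean1 - mean2), df, 0.0)
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(t), float(df), float(p))


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
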