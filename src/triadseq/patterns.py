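"""Hybrid-vs-midparent expression-pattern classification.

Each gene in a parent-parent-hybrid triad is assigned one of seven classes by
comparing the hybrid (F1) against the mid-parent value (MPV) and against each
parent with the pooled-count Fisher exact test (BH-adjusted separately within
each of the three comparison families):

    additive          F1 = MPV           (q_mpv >= alpha)
    over_dominant     F1 != MPV, F1 significantly above both parents
    under_dominant    F1 != MPV, F1 significantly below both parents
    parent1_dominant  F1 != MPV, F1 indistinguishable from parent 1 only
    parent2_dominant  F1 != MPV, F1 indistinguishable from parent 2 only
    conserved         F1 != MPV, different from both parents, yet strictly
                      inside the parental range
    ambiguous         F1 != MPV but none of the above applies

The MPV is materialised as a pseudo-sample whose per-gene count is the
(half-up rounded) mean of the two parents' pooled counts and whose library is
the mean of the parental pooled libraries, so the same exact test applies to
F1 vs MPV as to F1 vs each parent.

Because RNA-seq measures relative abundance, a shift in the expression of
one group of genes deflates the apparent rates of every other gene in that
library (composition bias).  By default each pairwise comparison therefore
uses an *effective* hybrid library rescaled so that the typical gene is
unchanged (20%-trimmed mean of per-gene log rate ratios over all genes, in
the spirit of TMM / median-of-ratios size factors); ``normalization="library"``
keeps the raw pooled library sums instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import ValidationError, percent
from .expression import (
    CountMatrix, SampleDesign, compute_fpkm, effective_library, pooled_counts,
)
from .stats import adjust_fdr, fisher_exact_vector

CLASSES = (
    "additive",
    "over_dominant",
    "under_dominant",
    "parent1_dominant",
    "parent2_dominant",
    "conserved",
    "ambiguous",
)
NON_ADDITIVE = CLASSES[1:]


@dataclass
class MpvProfile:
    """Mid-parent pseudo-sample: averaged pooled counts and library size."""

    pseudo_counts: pd.Series
    pseudo_library: int
    parents: tuple[str, str]


@dataclass
class PatternSummary:
    """Per-class counts with percentages on the full call set (2 dp)."""

    counts: dict[str, int]
    percentages: dict[str, float]
    additive_pct: float
    nonadditive_pct: float
    odo_udo_pct_of_nonadditive: float | None

    @property
    def n_additive(self) -> int:
        return self.counts["additive"]

    @property
    def n_nonadditive(self) -> int:
        return sum(self.counts[c] for c in NON_ADDITIVE)


def _round_half_up_series(x: pd.Series) -> pd.Series:
    return np.floor(x + 0.5).astype(np.int64)


def build_mpv(
    counts: CountMatrix, design: SampleDesign, parent1: str, parent2: str
) -> MpvProfile:
    """Average the two parents' pooled counts into a mid-parent pseudo-sample."""
    c1, l1 = pooled_counts(counts, design, parent1)
    c2, l2 = pooled_counts(counts, design, parent2)
    pseudo = _round_half_up_series((c1 + c2) / 2.0)
    lib = int(np.floor((l1 + l2) / 2.0 + 0.5))
    return MpvProfile(pseudo, lib, (parent1, parent2))


class PatternResults:
    """Per-gene pattern calls for one triad.

    ``table`` columns: pattern, q_mpv, q_p1, q_p2, rate_f1/p1/p2/mpv
    (pooled-count rates used for direction decisions).
    """

    def __init__(
        self, table: pd.DataFrame, hybrid: str, parent1: str, parent2: str, alpha: float
    ) -> None:
        self.table = table
        self.hybrid = hybrid
        self.parent1 = parent1
        self.parent2 = parent2
        self.alpha = alpha

    @property
    def calls(self) -> pd.Series:
        return self.table["pattern"]

    def pattern_summary(self) -> PatternSummary:
        return pattern_summary(self.calls)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def summary(self) -> str:
        s = self.pattern_summary()
        lines = [
            f"Expression-pattern classification: {self.hybrid} vs MPV"
            f"({self.parent1}, {self.parent2}), FDR < {self.alpha:g}",
            f"  genes classified : {len(self.table)}",
            f"  additive         : {s.counts['additive']} ({s.additive_pct:.2f}%)",
            f"  non-additive     : {s.n_nonadditive} ({s.nonadditive_pct:.2f}%)",
        ]
        for cls in NON_ADDITIVE:
            lines.append(f"    {cls:<17}: {s.counts[cls]}")
        if s.odo_udo_pct_of_nonadditive is not None:
            lines.append(
                "  over+under dominant share of non-additive: "
                f"{s.odo_udo_pct_of_nonadditive:.2f}%"
            )
        return "\n".join(lines)

    def plot_classes(self, ax=None):
        """Bar chart of class counts (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.pattern_summary()
        ax.bar(list(s.counts), list(s.counts.values()))
        ax.set_ylabel("genes")
        ax.set_title(f"{self.hybrid} expression patterns")
        ax.tick_params(axis="x", rotation=45)
        return ax


class PatternModel:
    """Classify hybrid expression patterns against the mid-parent value.

    Parameters
    ----------
    counts, design
        Triad count data; hybrid and both parents must be present.
    genes
        Optional gene subset to classify (e.g. a DEG list).  By default every
        gene expressed (mean FPKM >= ``expressed_threshold``) in at least one
        of the three genotypes is classified.
    alpha
        FDR threshold applied to each BH-adjusted comparison family.
    normalization
        "ratio" (default): rescale the hybrid library per comparison by the
        trimmed mean of log per-gene rate ratios, computed over *all* genes
        of the matrix, so composition shifts cancel.  "library": use the raw
        pooled library sums.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        hybrid: str,
        parent1: str,
        parent2: str,
        *,
        alpha: float = 0.05,
        genes: Iterable[str] | None = None,
        expressed_threshold: float = 1.0,
        normalization: str = "ratio",
    ) -> None:
        self.counts = counts
        self.design = design
        self.hybrid = hybrid
        self.parent1 = parent1
        self.parent2 = parent2
        self.alpha = alpha
        self.genes = None if genes is None else list(genes)
        self.expressed_threshold = expressed_threshold
        if normalization not in ("ratio", "library"):
            raise ValidationError(
                f"unknown normalization {normalization!r}; use 'ratio' or 'library'"
            )
        self.normalization = normalization
        for g in (hybrid, parent1, parent2):
            design.samples(g)

    def _gene_subset(self) -> pd.Index:
        if self.genes is not None:
            idx = pd.Index(self.genes)
            missing = idx.difference(self.counts.gene_ids)
            if len(missing):
                raise ValidationError(f"unknown gene ids: {list(missing[:5])}")
            return idx
        fpkm = compute_fpkm(self.counts)
        keep = None
        for g in (self.hybrid, self.parent1, self.parent2):
            mean = fpkm.values[self.design.samples(g)].mean(axis=1)
            ok = mean >= self.expressed_threshold
            keep = ok if keep is None else (keep | ok)
        return self.counts.gene_ids[keep]

    def fit(self) -> PatternResults:
        genes = self._gene_subset()
        cf1_all, lf1 = pooled_counts(self.counts, self.design, self.hybrid)
        cp1_all, lp1 = pooled_counts(self.counts, self.design, self.parent1)
        cp2_all, lp2 = pooled_counts(self.counts, self.design, self.parent2)
        mpv = build_mpv(self.counts, self.design, self.parent1, self.parent2)

        def compare(other_all: pd.Series, other_lib: int):
            if self.normalization == "ratio":
                f1_lib = effective_library(cf1_all, lf1, other_all, other_lib)
            else:
                f1_lib = lf1
            cf1 = cf1_all[genes]
            co = other_all[genes]
            q = adjust_fdr(
                fisher_exact_vector(cf1, f1_lib - cf1, co, other_lib - co),
                "bh", ids=genes,
            ).q
            return q, cf1.to_numpy() / f1_lib, co.to_numpy() / other_lib

        q_mpv, _, rate_mpv = compare(mpv.pseudo_counts, mpv.pseudo_library)
        q_p1, rate_f1_vs_p1, rate_p1 = compare(cp1_all, lp1)
        q_p2, rate_f1_vs_p2, rate_p2 = compare(cp2_all, lp2)

        pattern = classify_pattern(
            q_mpv, q_p1, q_p2,
            above_p1=rate_f1_vs_p1 > rate_p1,
            above_p2=rate_f1_vs_p2 > rate_p2,
            below_p1=rate_f1_vs_p1 < rate_p1,
            below_p2=rate_f1_vs_p2 < rate_p2,
            alpha=self.alpha,
        )
        table = pd.DataFrame(
            {
                "pattern": pattern,
                "q_mpv": q_mpv,
                "q_p1": q_p1,
                "q_p2": q_p2,
                "rate_f1": cf1_all[genes].to_numpy() / lf1,
                "rate_p1": rate_p1,
                "rate_p2": rate_p2,
                "rate_mpv": rate_mpv,
            },
            index=genes,
        )
        return PatternResults(table, self.hybrid, self.parent1, self.parent2, self.alpha)


def classify_pattern(
    q_mpv, q_p1, q_p2, above_p1, above_p2, below_p1, below_p2,
    alpha: float = 0.05,
) -> np.ndarray:
    """Vectorised decision tree over the three q-values and rate comparisons.

    ``above_p*`` / ``below_p*`` say whether the hybrid's (normalised) rate
    exceeds / falls short of each parent's.  Precedence among the
    non-additive classes is over/under-dominance, then single-parent
    dominance, then conserved; genes significant against the MPV that fit
    none of those (e.g. indistinguishable from both parents) are ambiguous.
    """
    q_mpv, q_p1, q_p2 = map(np.asarray, (q_mpv, q_p1, q_p2))
    above_p1, above_p2, below_p1, below_p2 = map(
        np.asarray, (above_p1, above_p2, below_p1, below_p2)
    )
    n = len(q_mpv)
    out = np.full(n, "ambiguous", dtype=object)

    additive = q_mpv >= alpha
    sig1 = q_p1 < alpha
    sig2 = q_p2 < alpha
    above_both = above_p1 & above_p2
    below_both = below_p1 & below_p2
    inside = (above_p1 & below_p2) | (below_p1 & above_p2)  # strict interior

    nonadd = ~additive
    out[additive] = "additive"
    out[nonadd & sig1 & sig2 & above_both] = "over_dominant"
    out[nonadd & sig1 & sig2 & below_both] = "under_dominant"
    out[nonadd & ~sig1 & sig2] = "parent1_dominant"
    out[nonadd & sig1 & ~sig2] = "parent2_dominant"
    out[nonadd & sig1 & sig2 & ~above_both & ~below_both & inside] = "conserved"
    return out


def pattern_summary(calls: pd.Series | Iterable[str]) -> PatternSummary:
    """Class counts and percentages; the over+under-dominant share is taken
    on the non-additive denominator (ambiguous counts as non-additive)."""
    calls = pd.Series(list(calls))
    counts = {cls: int((calls == cls).sum()) for cls in CLASSES}
    unknown = set(calls) - set(CLASSES)
    if unknown:
        raise ValidationError(f"unknown pattern classes {sorted(unknown)}")
    total = len(calls)
    if total == 0:
        raise ValidationError("no pattern calls to summarise")
    percentages = {cls: percent(cnt, total) for cls, cnt in counts.items()}
    n_nonadd = total - counts["additive"]
    odo_udo = (
        percent(counts["over_dominant"] + counts["under_dominant"], n_nonadd)
        if n_nonadd
        else None
    )
    return PatternSummary(
        counts=counts,
        percentages=percentages,
        additive_pct=percent(counts["additive"], total),
        nonadditive_pct=percent(n_nonadd, total),
        odo_udo_pct_of_nonadditive=odo_udo,
    )
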