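"""Differential expression between two genotypes and DEG set-partition logic.

Replicates are pooled within each genotype and every gene is tested with a
two-sided Fisher exact test on the 2x2 table

    [[pooled count in A, pooled library remainder in A],
     [pooled count in B, pooled library remainder in B]],

followed by Benjamini-Hochberg adjustment across the tested genes.  A gene is
only tested if it passes the expressed filter (mean FPKM >= threshold) in at
least one of the two genotypes, which keeps the BH denominator meaningful.
A dispersion-aware alternative (Welch t on log2 FPKM across replicates) is
available via ``method="welch"``.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import ValidationError, percent
from .expression import (
    CountMatrix, SampleDesign, compute_fpkm, effective_library, pooled_counts,
)
from .stats import adjust_fdr, fisher_exact_vector


@dataclass
class DegPartition:
    """Primary/secondary DEG sets with their shared and primary-unique parts."""

    primary: frozenset
    secondary: frozenset
    shared: frozenset
    unique: frozenset

    def to_dict(self) -> dict[str, int]:
        return {
            "primary": len(self.primary),
            "secondary": len(self.secondary),
            "shared": len(self.shared),
            "unique": len(self.unique),
        }


@dataclass
class UpDownSummary:
    n_up: int
    n_down: int
    pct_up: float | None
    pct_down: float | None


class DifferentialExpressionResults:
    """Per-gene differential-expression calls between two genotypes.

    ``table`` columns: fpkm_a, fpkm_b, log2fc (B over A, pseudocount applied),
    p, q, call in {up, down, ns}; "up" means genotype B exceeds genotype A.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        genotype_a: str,
        genotype_b: str,
        alpha: float,
        method: str,
        pseudocount: float,
    ) -> None:
        self.table = table
        self.genotype_a = genotype_a
        self.genotype_b = genotype_b
        self.alpha = alpha
        self.method = method
        self.pseudocount = pseudocount

    @property
    def deg_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "ns"])

    def updown_summary(self) -> UpDownSummary:
        return updown_summary(self.table["call"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def summary(self) -> str:
        ud = self.updown_summary()
        lines = [
            "Differential expression"
            f" ({self.genotype_b} vs {self.genotype_a}, {self.method},"
            f" FDR < {self.alpha:g}, log2FC pseudocount {self.pseudocount:g} FPKM)",
            f"  genes tested : {len(self.table)}",
            f"  DEGs         : {ud.n_up + ud.n_down}",
            f"  up   ({self.genotype_b} > {self.genotype_a}) : {ud.n_up}",
            f"  down ({self.genotype_b} < {self.genotype_a}) : {ud.n_down}",
        ]
        return "\n".join(lines)


class DifferentialExpressionModel:
    """Two-genotype differential expression on a count matrix.

    Parameters
    ----------
    counts, design
        Count matrix and sample design; both genotypes must be present.
    genotype_a, genotype_b
        Labels to compare; fold changes and "up" calls are B relative to A.
    alpha
        FDR threshold for a DEG call.
    method
        "fisher" (pooled-count exact test, default) or "welch" (t test on
        log2(FPKM + pseudocount) across replicates; needs >= 2 replicates).
    expressed_threshold
        Mean-FPKM filter a gene must pass in at least one genotype.
    pseudocount
        FPKM pseudocount used in the log2 fold change (and Welch transform).
    normalization
        "ratio" (default): the exact test uses an effective library for
        genotype B rescaled by the median per-gene rate ratio over all genes,
        cancelling composition bias.  "library": raw pooled library sums.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        genotype_a: str,
        genotype_b: str,
        *,
        alpha: float = 0.05,
        method: Literal["fisher", "welch"] = "fisher",
        expressed_threshold: float = 1.0,
        pseudocount: float = 1.0,
        normalization: str = "ratio",
    ) -> None:
        self.counts = counts
        self.design = design
        self.genotype_a = genotype_a
        self.genotype_b = genotype_b
        self.alpha = alpha
        self.method = method
        self.expressed_threshold = expressed_threshold
        self.pseudocount = pseudocount
        if normalization not in ("ratio", "library"):
            raise ValidationError(
                f"unknown normalization {normalization!r}; use 'ratio' or 'library'"
            )
        self.normalization = normalization
        design.samples(genotype_a)
        design.samples(genotype_b)

    def fit(self) -> DifferentialExpressionResults:
        cm, design = self.counts, self.design
        fpkm = compute_fpkm(cm)
        fa = fpkm.values[design.samples(self.genotype_a)].mean(axis=1)
        fb = fpkm.values[design.samples(self.genotype_b)].mean(axis=1)
        tested = cm.gene_ids[
            (fa >= self.expressed_threshold) | (fb >= self.expressed_threshold)
        ]
        fa, fb = fa[tested], fb[tested]
        if self.method == "fisher":
            ca_all, lib_a = pooled_counts(cm, design, self.genotype_a)
            cb_all, lib_b = pooled_counts(cm, design, self.genotype_b)
            if self.normalization == "ratio":
                lib_b = effective_library(cb_all, lib_b, ca_all, lib_a)
            ca, cb = ca_all[tested], cb_all[tested]
            p = fisher_exact_vector(ca, lib_a - ca, cb, lib_b - cb)
        elif self.method == "welch":
            la = np.log2(
                fpkm.values.loc[tested, design.samples(self.genotype_a)]
                + self.pseudocount
            )
            lb = np.log2(
                fpkm.values.loc[tested, design.samples(self.genotype_b)]
                + self.pseudocount
            )
            if la.shape[1] < 2 or lb.shape[1] < 2:
                raise ValidationError("welch method needs >= 2 replicates per genotype")
            res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
            p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        else:
            raise ValidationError(f"unknown method {self.method!r}")
        q = adjust_fdr(p, "bh", ids=tested).q
        log2fc = np.log2((fb + self.pseudocount) / (fa + self.pseudocount))
        call = np.where(
            q < self.alpha, np.where(log2fc > 0, "up", "down"), "ns"
        )
        # a significant q with exactly zero fold change is not directional
        call = np.where((call != "ns") & (log2fc == 0), "ns", call)
        table = pd.DataFrame(
            {
                "fpkm_a": fa,
                "fpkm_b": fb,
                "log2fc": log2fc,
                "p": p,
                "q": q,
                "call": call,
            },
            index=tested,
        )
        return DifferentialExpressionResults(
            table, self.genotype_a, self.genotype_b, self.alpha,
            self.method, self.pseudocount,
        )


def call_degs(
    counts: CountMatrix,
    design: SampleDesign,
    genotype_a: str,
    genotype_b: str,
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around DifferentialExpressionModel; returns the table."""
    model = DifferentialExpressionModel(
        counts, design, genotype_a, genotype_b, alpha=alpha, **kwargs
    )
    return model.fit().table


def partition_unique_degs(primary: Iterable, secondary: Iterable) -> DegPartition:
    """Split the primary DEG set by membership in the secondary comparison.

    ``shared`` genes appear in both comparisons; ``unique`` = primary \\ shared,
    so |unique| = |primary| - |shared| always holds.
    """
    primary = frozenset(primary)
    secondary = frozenset(secondary)
    shared = primary & secondary
    return DegPartition(primary, secondary, shared, primary - shared)


def updown_summary(calls: pd.Series | Iterable[str]) -> UpDownSummary:
    """Counts and percentages (2 dp) of up/down calls among called genes."""
    calls = pd.Series(list(calls))
    n_up = int((calls == "up").sum())
    n_down = int((calls == "down").sum())
    total = n_up + n_down
    if total == 0:
        return UpDownSummary(0, 0, None, None)
    return UpDownSummary(n_up, n_down, percent(n_up, total), percent(n_down, total))
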