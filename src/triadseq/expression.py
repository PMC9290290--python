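"""Count matrices, sample designs, FPKM normalisation and expression filters.

The basic substrate is a gene x sample table of raw fragment counts together
with per-gene exonic lengths.  Expression levels are reported as FPKM
(fragments per kilobase of exon model per million mapped fragments):

    FPKM(g, s) = 1e9 * count(g, s) / (length_bp(g) * library_size(s))

Library sizes default to the column sums of the count matrix.  A gene is
considered *expressed* in a genotype when its FPKM, averaged over that
genotype's replicates, reaches a threshold (1 FPKM by default); expressed
genes are further binned into low / medium / high expression classes at
20 and 50 FPKM.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from ._util import ValidationError, percent

ROLES = ("parent1", "parent2", "hybrid", "other")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer read counts per (gene, sample) with gene lengths in bp.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; values must
        be non-negative integers.
    gene_lengths
        Series of positive exonic lengths (bp) aligned to ``counts.index``.
    library_sizes
        Optional per-sample totals; column sums of ``counts`` when omitted.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate gene ids in count matrix")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValidationError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        gl = self.gene_lengths.reindex(c.index)
        if gl.isna().any():
            missing = list(gl.index[gl.isna()])[:5]
            raise ValidationError(f"gene lengths missing for {missing}")
        if (gl <= 0).any():
            raise ValidationError("gene lengths must be positive")
        self.gene_lengths = gl.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            ls = self.library_sizes.reindex(c.columns)
            if ls.isna().any() or (ls <= 0).any():
                raise ValidationError("library sizes must be positive for every sample")
            self.library_sizes = ls.astype(np.int64)
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive for every sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(
            self.counts[samples], self.gene_lengths, self.library_sizes[samples]
        )


@dataclass
class FpkmMatrix:
    """Length- and depth-normalised expression values on the same axes."""

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleDesign:
    """Maps sample ids to (genotype, role, replicate).

    ``role`` is one of parent1 / parent2 / hybrid / other and records the
    position of a genotype inside a parent-parent-hybrid triad; the genotype
    label is what analysis functions address samples by.
    """

    table: pd.DataFrame  # index sample_id; columns genotype, role, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = {"genotype", "role", "replicate"}
        if not required.issubset(t.columns):
            raise ValidationError(f"design table needs columns {sorted(required)}")
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        if (t["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        dup = t.duplicated(subset=["genotype", "replicate"])
        if dup.any():
            raise ValidationError(
                f"duplicate (genotype, replicate) pairs: {list(t.index[dup])}"
            )
        t = t.copy()
        t["replicate"] = t["replicate"].astype(int)
        self.table = t

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    def samples(self, genotype: str) -> list[str]:
        hits = self.table.index[self.table["genotype"] == genotype]
        if len(hits) == 0:
            raise ValidationError(f"unknown genotype label {genotype!r}")
        return list(hits)


@dataclass
class ExpressionBins:
    """Counts of expressed genes per level bin; fractions are None when empty."""

    high: int
    medium: int
    low: int
    low_pct: float | None = field(default=None)

    @property
    def total(self) -> int:
        return self.high + self.medium + self.low


# ---------------------------------------------------------------------------
# I/O — tab-delimited, UTF-8, '#' comments
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> CountMatrix:
    """Read a count TSV: columns gene_id, gene_length_bp, then one per sample."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValidationError("count TSV needs gene_id, gene_length_bp and >=1 sample")
    df = df.set_index(df.columns[0])
    lengths = df.iloc[:, 0]
    counts = df.iloc[:, 1:]
    return CountMatrix(counts, lengths)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_length_bp", cm.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = ["sample_id", "genotype", "role", "replicate"]
    if list(df.columns[:4]) != needed:
        raise ValidationError(f"design TSV must start with columns {needed}")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_fpkm(cm: CountMatrix) -> FpkmMatrix:
    """FPKM(g, s) = 1e9 * count / (gene_length_bp * library_size)."""
    lengths = cm.gene_lengths.to_numpy()[:, None].astype(float)
    libs = cm.library_sizes.to_numpy()[None, :].astype(float)
    values = 1e9 * cm.counts.to_numpy(dtype=float) / (lengths * libs)
    return FpkmMatrix(
        pd.DataFrame(values, index=cm.gene_ids, columns=cm.sample_ids),
        cm.gene_lengths,
    )


def invert_fpkm(fpkm: FpkmMatrix, library_sizes: pd.Series) -> pd.DataFrame:
    """Recover (rounded) counts from FPKM values — the round trip of compute_fpkm."""
    if fpkm.gene_lengths is None:
        raise ValidationError("gene lengths required to invert FPKM")
    lengths = fpkm.gene_lengths.to_numpy()[:, None].astype(float)
    libs = library_sizes.reindex(fpkm.sample_ids).to_numpy()[None, :].astype(float)
    counts = fpkm.values.to_numpy() * lengths * libs / 1e9
    return pd.DataFrame(
        np.rint(counts).astype(np.int64), index=fpkm.gene_ids, columns=fpkm.sample_ids
    )


def genotype_mean_fpkm(
    fpkm: FpkmMatrix, design: SampleDesign, genotype: str
) -> pd.Series:
    """Mean FPKM across the replicates of one genotype."""
    return fpkm.values[design.samples(genotype)].mean(axis=1)


def expressed_genes(
    fpkm: FpkmMatrix,
    design: SampleDesign,
    genotype: str,
    threshold: float = 1.0,
    how: Literal["mean", "any"] = "mean",
) -> set[str]:
    """Genes expressed in ``genotype``: mean (default) or any replicate FPKM >= threshold."""
    sub = fpkm.values[design.samples(genotype)]
    if how == "mean":
        keep = sub.mean(axis=1) >= threshold
    elif how == "any":
        keep = (sub >= threshold).any(axis=1)
    else:
        raise ValidationError(f"unknown replicate rule {how!r}; use 'mean' or 'any'")
    return set(sub.index[keep])


def expression_bins(
    values: Iterable[float],
    expressed_threshold: float = 1.0,
    medium: float = 20.0,
    high: float = 50.0,
) -> ExpressionBins:
    """Bin expressed FPKM values: high [50, inf), medium [20, 50), low [1, 20).

    Boundaries are left-closed, so FPKM exactly 50 is "high" and exactly 20 is
    "medium".  The low-expression share is reported as a percentage (2 dp);
    it is None for empty input.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (arr < expressed_threshold).any():
        raise ValidationError(
            f"all inputs must be expressed (>= {expressed_threshold} FPKM)"
        )
    n_high = int((arr >= high).sum())
    n_medium = int(((arr >= medium) & (arr < high)).sum())
    n_low = int((arr < medium).sum())
    low_pct = percent(n_low, arr.size) if arr.size else None
    return ExpressionBins(high=n_high, medium=n_medium, low=n_low, low_pct=low_pct)


def pooled_counts(
    cm: CountMatrix, design: SampleDesign, genotype: str
) -> tuple[pd.Series, int]:
    """Sum counts over a genotype's replicates; returns (per-gene sums, pooled library)."""
    samples = design.samples(genotype)
    pooled = cm.counts[samples].sum(axis=1)
    lib = int(cm.library_sizes[samples].sum())
    return pooled, lib


def effective_library(
    counts_x: pd.Series, lib_x: int, counts_y: pd.Series, lib_y: int
) -> int:
    """Rescale lib_x so the typical gene has equal rates in the two profiles.

    Sequencing measures relative abundance, so shifting one group of genes
    deflates the apparent rates of every other gene in that library
    (composition bias).  The returned effective library is lib_x times the
    median per-gene rate ratio over genes observed in both profiles
    (median-of-ratios); using it in a rate comparison centres the typical
    gene's ratio at 1.
    """
    both = (counts_x > 0) & (counts_y > 0)
    if both.sum() < 3:
        return lib_x
    logr = np.log(
        (counts_x[both].to_numpy() / lib_x) / (counts_y[both].to_numpy() / lib_y)
    )
    scale = float(np.exp(np.median(logr)))
    return max(1, int(np.floor(lib_x * scale + 0.5)))
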