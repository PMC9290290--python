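"""Allele-specific expression (ASE) calling from SNP-level allelic read counts.

At every SNP inside a gene the hybrid's reads are split between the two
parental alleles.  The allele-specific expression level is

    P = reads_allele1 / (reads_allele0 + reads_allele1),

where allele 1 is the tester-line allele and allele 0 the other parent's
(P = 0: only allele 0 expressed; P = 0.5: balanced; P = 1: only allele 1).
Each SNP is tested against a balanced 0.5 ratio with an exact two-sided
binomial test, BH-adjusted across all testable SNPs of a hybrid.  A gene is
called ASE when it carries at least ``min_snps`` significant SNPs biased to
the same side of 0.5 and its gene-level P (read-weighted mean over SNPs, or
a pooled-read ratio) lies outside the [p_lo, p_hi] balance band.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from ._util import ValidationError, percent
from .stats import adjust_fdr, binom_two_sided

SNP_COLUMNS = ["hybrid_id", "chrom", "pos", "gene_id", "reads_allele0", "reads_allele1"]


@dataclass
class AseSummary:
    n_analyzed: int
    n_ase: int
    ratio_pct: float


@dataclass
class AseOverlap:
    """Three-way split of DEGs showing ASE in two hybrids."""

    both: frozenset
    only_h1: frozenset
    only_h2: frozenset

    def to_dict(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "only_h1": len(self.only_h1),
            "only_h2": len(self.only_h2),
        }


def snp_ratio(reads_allele0: int, reads_allele1: int) -> float:
    """Allele-specific expression level P at one SNP."""
    total = reads_allele0 + reads_allele1
    if reads_allele0 < 0 or reads_allele1 < 0:
        raise ValidationError("allele read counts must be non-negative")
    if total < 1:
        raise ValidationError("SNP with zero total reads is untestable")
    return reads_allele1 / total


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    """Read the SNP allele-count TSV (hybrid_id, chrom, pos, gene_id, reads)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"hybrid_id": str, "chrom": str, "gene_id": str},
    )
    if list(df.columns[: len(SNP_COLUMNS)]) != SNP_COLUMNS:
        raise ValidationError(f"SNP TSV must start with columns {SNP_COLUMNS}")
    return validate_snp_table(df)


def write_snp_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_vcf_allele_counts(
    path: str | Path, hybrid_id: str, gene_field: str = "GENE"
) -> pd.DataFrame:
    """Read a minimal VCF dialect: AD on the single sample, gene id in INFO.

    The first AD value maps to allele 0 (REF, the non-tester parent's allele)
    and the second to allele 1 (ALT, the tester allele).
    """
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValidationError("VCF record without a sample column")
            chrom, pos, _, _, _, _, _, info, fmt, sample = parts[:10]
            info_map = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            if gene_field not in info_map:
                raise ValidationError(f"INFO field {gene_field} missing at {chrom}:{pos}")
            fmt_keys = fmt.split(":")
            if "AD" not in fmt_keys:
                raise ValidationError(f"AD missing from FORMAT at {chrom}:{pos}")
            ad = sample.split(":")[fmt_keys.index("AD")].split(",")
            rows.append(
                {
                    "hybrid_id": hybrid_id,
                    "chrom": chrom,
                    "pos": int(pos),
                    "gene_id": info_map[gene_field],
                    "reads_allele0": int(ad[0]),
                    "reads_allele1": int(ad[1]),
                }
            )
    return validate_snp_table(pd.DataFrame(rows, columns=SNP_COLUMNS))


def validate_snp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the SNP-table invariants (unique positions, consistent genes)."""
    if (df[["reads_allele0", "reads_allele1"]].to_numpy() < 0).any():
        raise ValidationError("negative allele read counts")
    dup = df.duplicated(subset=["hybrid_id", "chrom", "pos"])
    if dup.any():
        where = df.loc[dup, ["hybrid_id", "chrom", "pos"]].iloc[0].tolist()
        raise ValidationError(f"duplicate SNP position {where}")
    # a (chrom, pos) must not map to different genes across hybrids
    ngenes = df.groupby(["chrom", "pos"])["gene_id"].nunique()
    if (ngenes > 1).any():
        bad = ngenes.index[ngenes > 1][0]
        raise ValidationError(f"SNP {bad} assigned to multiple genes")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    return df


class ASEResults:
    """Gene-level ASE calls per hybrid.

    ``table`` is indexed by (hybrid_id, gene_id) with columns n_snps_total,
    n_snps_significant, ase_level (gene-level P), direction and is_ase;
    ``snp_table`` carries the per-SNP P, p and q values.
    """

    def __init__(
        self, table: pd.DataFrame, snp_table: pd.DataFrame, alpha: float,
        p_lo: float, p_hi: float, min_snps: int,
    ) -> None:
        self.table = table
        self.snp_table = snp_table
        self.alpha = alpha
        self.p_lo = p_lo
        self.p_hi = p_hi
        self.min_snps = min_snps

    @property
    def hybrids(self) -> list[str]:
        return list(self.table.index.get_level_values(0).unique())

    def gene_calls(self, hybrid_id: str) -> set[str]:
        sub = self.table.loc[hybrid_id]
        return set(sub.index[sub["is_ase"]])

    def analyzed_genes(self, hybrid_id: str) -> set[str]:
        return set(self.table.loc[hybrid_id].index)

    def ase_summary(self, hybrid_id: str) -> AseSummary:
        sub = self.table.loc[hybrid_id]
        return ase_summary(int(sub["is_ase"].sum()), len(sub))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    def summary(self) -> str:
        lines = [
            f"Allele-specific expression (binomial vs 0.5, FDR < {self.alpha:g}, "
            f">= {self.min_snps} concordant SNPs, P outside "
            f"[{self.p_lo:g}, {self.p_hi:g}])"
        ]
        for h in self.hybrids:
            s = self.ase_summary(h)
            lines.append(
                f"  {h}: {s.n_ase} ASE genes of {s.n_analyzed} analyzed"
                f" ({s.ratio_pct:.2f}%)"
            )
        return "\n".join(lines)


class ASEModel:
    """Call ASE genes from a SNP allele-count table (possibly several hybrids).

    Parameters
    ----------
    snps
        Validated SNP table with columns ``SNP_COLUMNS``; SNPs with zero total
        reads are dropped (untestable) before analysis.
    rule
        "strict": at least ``min_snps`` BH-significant SNPs biased to the same
        side of 0.5.  "relaxed": at least ``min_snps`` testable SNPs and a
        significant pooled-read binomial test for the gene (BH across genes).
    aggregation
        Gene-level P as a read-weighted mean of SNP P values ("weighted",
        default) or as the pooled-read ratio ("pooled"); the two coincide
        when every SNP has equal depth.
    """

    def __init__(
        self,
        snps: pd.DataFrame,
        *,
        alpha: float = 0.05,
        p_hi: float = 0.6,
        p_lo: float = 0.4,
        min_snps: int = 2,
        rule: Literal["strict", "relaxed"] = "strict",
        aggregation: Literal["weighted", "pooled"] = "weighted",
        midp: bool = False,
    ) -> None:
        self.snps = validate_snp_table(snps)
        self.alpha = alpha
        self.p_hi = p_hi
        self.p_lo = p_lo
        self.min_snps = min_snps
        self.rule = rule
        self.aggregation = aggregation
        self.midp = midp

    def fit(self) -> ASEResults:
        df = self.snps.copy()
        df["total"] = df["reads_allele0"] + df["reads_allele1"]
        df = df[df["total"] >= 1].copy()  # untestable SNPs excluded
        if df.empty:
            raise ValidationError("no testable SNPs")
        df["snp_p_level"] = df["reads_allele1"] / df["total"]
        df["p"] = [
            binom_two_sided(int(k), int(n), 0.5, midp=self.midp)
            for k, n in zip(df["reads_allele1"], df["total"])
        ]
        # BH family: all testable SNPs of one hybrid
        df["q"] = np.nan
        for h, idx in df.groupby("hybrid_id").groups.items():
            df.loc[idx, "q"] = adjust_fdr(df.loc[idx, "p"], "bh", ids=idx).q

        gene_rows = []
        for (h, g), sub in df.groupby(["hybrid_id", "gene_id"], sort=True):
            weights = sub["total"].to_numpy(dtype=float)
            if self.aggregation == "weighted":
                level = float(np.average(sub["snp_p_level"], weights=weights))
            elif self.aggregation == "pooled":
                level = float(sub["reads_allele1"].sum() / sub["total"].sum())
            else:
                raise ValidationError(f"unknown aggregation {self.aggregation!r}")
            sig = sub["q"] < self.alpha
            n_sig_hi = int((sig & (sub["snp_p_level"] > 0.5)).sum())
            n_sig_lo = int((sig & (sub["snp_p_level"] < 0.5)).sum())
            outside = level > self.p_hi or level < self.p_lo
            if self.rule == "strict":
                concordant = max(n_sig_hi, n_sig_lo)
                is_ase = concordant >= self.min_snps and outside
            elif self.rule == "relaxed":
                pooled_k = int(sub["reads_allele1"].sum())
                pooled_n = int(sub["total"].sum())
                gene_p = binom_two_sided(pooled_k, pooled_n, 0.5, midp=self.midp)
                is_ase = len(sub) >= self.min_snps and outside and gene_p < self.alpha
            else:
                raise ValidationError(f"unknown rule {self.rule!r}")
            direction = (
                "toward_allele1" if level > 0.5
                else "toward_allele0" if level < 0.5
                else "balanced"
            )
            gene_rows.append(
                {
                    "hybrid_id": h,
                    "gene_id": g,
                    "n_snps_total": len(sub),
                    "n_snps_significant": int(sig.sum()),
                    "ase_level": level,
                    "direction": direction,
                    "is_ase": bool(is_ase),
                }
            )
        table = pd.DataFrame(gene_rows).set_index(["hybrid_id", "gene_id"])
        return ASEResults(table, df, self.alpha, self.p_lo, self.p_hi, self.min_snps)


def call_ase_genes(
    snps: pd.DataFrame,
    alpha: float = 0.05,
    p_hi: float = 0.6,
    p_lo: float = 0.4,
    min_snps: int = 2,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around ASEModel; returns the gene-level table."""
    model = ASEModel(
        snps, alpha=alpha, p_hi=p_hi, p_lo=p_lo, min_snps=min_snps, **kwargs
    )
    return model.fit().table


def ase_summary(n_ase: int, n_genes_analyzed: int) -> AseSummary:
    """ASE gene count and percentage of the analyzed genes (2 dp)."""
    if n_genes_analyzed <= 0:
        raise ValidationError("analyzed-gene denominator must be positive")
    if n_ase > n_genes_analyzed:
        raise ValidationError("more ASE genes than analyzed genes")
    return AseSummary(n_genes_analyzed, n_ase, percent(n_ase, n_genes_analyzed))


def ase_deg_overlap(
    ase_h1: Iterable, ase_h2: Iterable, degs: Iterable
) -> AseOverlap:
    """Restrict both hybrids' ASE sets to the DEG list and split three ways."""
    degs = frozenset(degs)
    a1 = frozenset(ase_h1) & degs
    a2 = frozenset(ase_h2) & degs
    both = a1 & a2
    return AseOverlap(both, a1 - both, a2 - both)
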