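"""Annotation-driven over-representation analysis (hypergeometric test).

Given a study gene set drawn from a declared population and a flat gene-to-
term annotation table, each term is scored with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the population size, K the term's population hits, n the study
size and k the term's study hits.  q-values come from BH or BY adjustment
across terms (BY, valid under arbitrary dependence between overlapping
terms, is the default).  The rich factor k / K accompanies every term.  The
annotation table is taken as already propagated; no ontology-graph rollup is
performed here.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

from ._util import ValidationError
from .stats import FdrMethod, adjust_fdr

ANNOTATION_COLUMNS = ["gene_id", "term_id", "term_name", "category"]
CATEGORIES = ("BP", "MF", "CC", "other")


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    category: str
    genes: frozenset


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[: len(ANNOTATION_COLUMNS)]) != ANNOTATION_COLUMNS:
        raise ValidationError(f"annotation TSV must start with {ANNOTATION_COLUMNS}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"unknown categories {sorted(bad)}; expected {CATEGORIES}")
    return df


def annotation_terms(df: pd.DataFrame) -> list[TermAnnotation]:
    """Collapse a flat annotation table into one record per term."""
    out = []
    for term_id, sub in df.groupby("term_id", sort=True):
        names = sub["term_name"].unique()
        cats = sub["category"].unique()
        if len(names) > 1 or len(cats) > 1:
            raise ValidationError(f"inconsistent name/category for term {term_id}")
        out.append(
            TermAnnotation(term_id, names[0], cats[0], frozenset(sub["gene_id"]))
        )
    return out


class EnrichmentResults:
    """Per-term over-representation results sorted by q then p."""

    def __init__(self, table: pd.DataFrame, method: str, alpha: float) -> None:
        self.table = table
        self.method = method
        self.alpha = alpha

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"Enrichment ({self.method.upper()} FDR < {self.alpha:g}): "
            f"{len(self.significant)} of {len(self.table)} terms significant"
        ]
        for _, row in self.significant.head(10).iterrows():
            lines.append(
                f"  {row['term_id']:<12} {row['term_name']:<30.30} "
                f"k/K={row['k']}/{row['K']} rich={row['rich_factor']:.3f} "
                f"q={row['q']:.3g}"
            )
        return "\n".join(lines)


class EnrichmentModel:
    """Hypergeometric over-representation of a study set against a population."""

    def __init__(
        self,
        study: Iterable,
        population: Iterable,
        annotations: pd.DataFrame | Iterable[TermAnnotation],
        *,
        method: FdrMethod = "by",
        alpha: float = 0.05,
    ) -> None:
        self.study = frozenset(study)
        self.population = frozenset(population)
        outside = self.study - self.population
        if outside:
            raise ValidationError(
                f"study genes outside the population: {sorted(outside)[:10]}"
            )
        if isinstance(annotations, pd.DataFrame):
            annotations = annotation_terms(annotations)
        self.terms = list(annotations)
        for t in self.terms:
            stray = t.genes - self.population
            if stray:
                raise ValidationError(
                    f"term {t.term_id} annotates genes outside the population: "
                    f"{sorted(stray)[:10]}"
                )
        self.method = method
        self.alpha = alpha

    def fit(self) -> EnrichmentResults:
        N, n = len(self.population), len(self.study)
        rows = []
        for t in self.terms:
            K = len(t.genes)
            k = len(t.genes & self.study)
            p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            rows.append(
                {
                    "term_id": t.term_id,
                    "term_name": t.term_name,
                    "category": t.category,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": min(p, 1.0),
                    "rich_factor": k / K if K else 0.0,
                }
            )
        table = pd.DataFrame(
            rows,
            columns=[
                "term_id", "term_name", "category",
                "k", "n", "K", "N", "p", "rich_factor",
            ],
        )
        if len(table):
            table["q"] = adjust_fdr(table["p"], self.method, ids=table["term_id"]).q
            table["significant"] = table["q"] < self.alpha
            table = table.sort_values(["q", "p", "term_id"]).reset_index(drop=True)
        else:
            table["q"] = []
            table["significant"] = []
        return EnrichmentResults(table, self.method, self.alpha)


def enrich(
    study: Iterable,
    population: Iterable,
    annotations: pd.DataFrame | Iterable[TermAnnotation],
    method: FdrMethod = "by",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional wrapper around EnrichmentModel; returns the term table."""
    return EnrichmentModel(
        study, population, annotations, method=method, alpha=alpha
    ).fit().table
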