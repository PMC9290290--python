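"""End-to-end orchestration: expression -> DEG -> partition -> patterns ->
ASE -> overlap -> enrichment -> phenotype, driven by a RunConfig.

Every threshold the stages apply is a config field with the package default
(DEG/pattern/ASE FDR 0.05; ASE band 0.4/0.6 with >= 2 SNPs; expressed filter
1 FPKM with 20/50 bin edges); the summary JSON logs the values actually used.
Each stage writes its own TSV so stages can be re-run from intermediates.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._util import PipelineError, ValidationError
from . import ase as ase_mod
from . import enrichment as enrich_mod
from .degs import DifferentialExpressionModel, partition_unique_degs, updown_summary
from .expression import (
    compute_fpkm, expressed_genes, expression_bins, read_counts, read_design,
    write_counts, write_design,
)
from .patterns import PatternModel
from .phenotype import HeterosisModel, read_traits


@dataclass
class TriadSpec:
    """Genotype labels of one parent-parent-hybrid triad."""

    name: str
    parent1: str
    parent2: str
    hybrid: str


@dataclass
class RunConfig:
    """Inputs, triad roles and thresholds for a full pipeline run."""

    counts: str
    design: str
    triads: list[TriadSpec]
    snps: dict[str, str] = field(default_factory=dict)  # hybrid genotype -> TSV
    traits: str | None = None
    annotations: str | None = None
    trait_hybrid: str | None = None
    trait_check: str | None = None
    outdir: str = "triadseq_out"
    alpha_deg: float = 0.05
    alpha_pattern: float = 0.05
    alpha_ase: float = 0.05
    ase_p_hi: float = 0.6
    ase_p_lo: float = 0.4
    ase_min_snps: int = 2
    fpkm_expressed: float = 1.0
    fpkm_medium: float = 20.0
    fpkm_high: float = 50.0
    enrichment_method: str = "by"
    seed: int = 0

    def __post_init__(self) -> None:
        self.triads = [
            t if isinstance(t, TriadSpec) else TriadSpec(**t) for t in self.triads
        ]
        if len(self.triads) != 2:
            raise ValidationError("run-all needs exactly two triads (test and check)")
        for a in (self.alpha_deg, self.alpha_pattern, self.alpha_ase):
            if not 0 <= a <= 1:
                raise ValidationError("alpha thresholds must lie in [0, 1]")
        if not 0 <= self.ase_p_lo < self.ase_p_hi <= 1:
            raise ValidationError("need 0 <= ase_p_lo < ase_p_hi <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # tag the failing stage
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def run_all(config: RunConfig) -> dict:
    """Execute every stage for which inputs are configured; returns the summary.

    Writes per-stage TSVs plus ``summary.json`` into ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": _thresholds(config)}

    counts, design = _load_inputs(config)
    triad1, triad2 = config.triads

    fpkm = _expression_stage(config, counts, design, out, summary)
    primary, secondary = _deg_stage(config, counts, design, out, summary)
    part = _partition_stage(primary, secondary, out, summary)
    unique = sorted(part.unique)
    _pattern_stage(config, counts, design, unique, out, summary)
    ase_calls = _ase_stage(config, out, summary)
    _overlap_stage(config, ase_calls, part, out, summary)
    _enrichment_stage(config, unique, fpkm, design, out, summary)
    _phenotype_stage(config, out, summary)

    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _thresholds(config: RunConfig) -> dict:
    keys = [
        "alpha_deg", "alpha_pattern", "alpha_ase", "ase_p_hi", "ase_p_lo",
        "ase_min_snps", "fpkm_expressed", "fpkm_medium", "fpkm_high",
        "enrichment_method",
    ]
    return {k: getattr(config, k) for k in keys}


@_stage("load")
def _load_inputs(config: RunConfig):
    return read_counts(config.counts), read_design(config.design)


@_stage("expression")
def _expression_stage(config, counts, design, out, summary):
    fpkm = compute_fpkm(counts)
    fpkm.values.rename_axis("gene_id").to_csv(out / "fpkm.tsv", sep="\t")
    expr = {}
    for g in design.genotypes:
        genes = expressed_genes(fpkm, design, g, threshold=config.fpkm_expressed)
        values = fpkm.values.loc[sorted(genes), design.samples(g)].mean(axis=1)
        bins = expression_bins(
            values, config.fpkm_expressed, config.fpkm_medium, config.fpkm_high
        )
        expr[g] = {
            "expressed_n": len(genes),
            "high_n": bins.high,
            "medium_n": bins.medium,
            "low_n": bins.low,
            "low_pct": bins.low_pct,
        }
    summary["expression"] = expr
    return fpkm


@_stage("deg")
def _deg_stage(config, counts, design, out, summary):
    t1, t2 = config.triads
    res_primary = DifferentialExpressionModel(
        counts, design, t2.hybrid, t1.hybrid,
        alpha=config.alpha_deg, expressed_threshold=config.fpkm_expressed,
    ).fit()
    res_secondary = DifferentialExpressionModel(
        counts, design, t2.parent1, t1.parent1,
        alpha=config.alpha_deg, expressed_threshold=config.fpkm_expressed,
    ).fit()
    res_primary.to_tsv(out / "degs_hybrids.tsv")
    res_secondary.to_tsv(out / "degs_parents.tsv")
    ud = res_primary.updown_summary()
    summary["degs"] = {
        "primary_n": len(res_primary.deg_ids),
        "secondary_n": len(res_secondary.deg_ids),
        "primary_up_n": ud.n_up,
        "primary_down_n": ud.n_down,
    }
    return res_primary.deg_ids, res_secondary.deg_ids


@_stage("partition")
def _partition_stage(primary, secondary, out, summary):
    part = partition_unique_degs(primary, secondary)
    with open(out / "partition.json", "wt", encoding="utf-8") as fh:
        json.dump(part.to_dict(), fh, indent=2)
    summary["partition"] = part.to_dict()
    return part


@_stage("patterns")
def _pattern_stage(config, counts, design, unique, out, summary):
    patterns = {}
    for triad in config.triads:
        genes = [g for g in unique if g in counts.gene_ids]
        res = PatternModel(
            counts, design, triad.hybrid, triad.parent1, triad.parent2,
            alpha=config.alpha_pattern,
            genes=genes or None,
            expressed_threshold=config.fpkm_expressed,
        ).fit()
        res.to_tsv(out / f"patterns_{triad.name}.tsv")
        s = res.pattern_summary()
        patterns[triad.name] = {
            "additive_n": s.counts["additive"],
            "nonadditive_n": s.n_nonadditive,
            "additive_pct": s.additive_pct,
            "nonadditive_pct": s.nonadditive_pct,
            "odo_udo_pct_of_nonadditive": s.odo_udo_pct_of_nonadditive,
            **{f"{cls}_n": s.counts[cls] for cls in s.counts},
        }
    summary["patterns"] = patterns
    # promote the test triad's headline numbers to the top level
    first = patterns[config.triads[0].name]
    summary["additive_n"] = first["additive_n"]
    summary["nonadditive_n"] = first["nonadditive_n"]


@_stage("ase")
def _ase_stage(config, out, summary):
    ase_calls: dict[str, set] = {}
    ase_summaries = {}
    for hybrid, path in config.snps.items():
        snps = ase_mod.read_snp_counts(path)
        res = ase_mod.ASEModel(
            snps, alpha=config.alpha_ase, p_hi=config.ase_p_hi,
            p_lo=config.ase_p_lo, min_snps=config.ase_min_snps,
        ).fit()
        res.to_tsv(out / f"ase_{hybrid}.tsv")
        s = res.ase_summary(hybrid)
        ase_calls[hybrid] = res.gene_calls(hybrid)
        ase_summaries[hybrid] = {
            "analyzed_n": s.n_analyzed, "ase_n": s.n_ase, "ratio_pct": s.ratio_pct,
        }
    summary["ase"] = ase_summaries
    summary["ase_n"] = sum(v["ase_n"] for v in ase_summaries.values())
    return ase_calls


@_stage("overlap")
def _overlap_stage(config, ase_calls, part, out, summary):
    t1, t2 = config.triads
    if t1.hybrid in ase_calls and t2.hybrid in ase_calls:
        ov = ase_mod.ase_deg_overlap(
            ase_calls[t1.hybrid], ase_calls[t2.hybrid], part.unique
        )
        with open(out / "ase_deg_overlap.json", "wt", encoding="utf-8") as fh:
            json.dump(ov.to_dict(), fh, indent=2)
        summary["ase_deg_overlap"] = ov.to_dict()


@_stage("enrichment")
def _enrichment_stage(config, unique, fpkm, design, out, summary):
    if not config.annotations:
        return
    ann = enrich_mod.read_annotations(config.annotations)
    # population: expressed-gene universe of the test hybrid; annotations are
    # trimmed to it so term sets stay subsets of the population
    population = expressed_genes(
        fpkm, design, config.triads[0].hybrid, threshold=config.fpkm_expressed
    )
    ann = ann[ann["gene_id"].isin(population)]
    study = set(unique) & population
    if not study or ann.empty:
        summary["enrichment"] = {"terms_n": 0, "significant_n": 0}
        return
    res = enrich_mod.EnrichmentModel(
        study, population, ann, method=config.enrichment_method,
        alpha=config.alpha_pattern,
    ).fit()
    res.to_tsv(out / "enrichment.tsv")
    summary["enrichment"] = {
        "terms_n": len(res.table),
        "significant_n": len(res.significant),
    }


@_stage("phenotype")
def _phenotype_stage(config, out, summary):
    if not config.traits:
        return
    traits = read_traits(config.traits)
    hybrid = config.trait_hybrid or config.triads[0].hybrid
    check = config.trait_check or config.triads[1].hybrid
    res = HeterosisModel(traits, hybrid, check).fit()
    res.to_tsv(out / "phenotype.tsv")
    avg = res.table[res.table["environment"] == "Average"]
    summary["phenotype"] = {
        row["trait"]: {"over_check_pct_avg": row["over_check_pct"]}
        for _, row in avg.iterrows()
    }


def write_simulated_study(study: dict, outdir: str | Path, config) -> RunConfig:
    """Write a simulate_study() bundle as pipeline-ready input files + config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(study["counts"], out / "counts.tsv")
    write_design(study["design"], out / "design.tsv")
    study["truth"].to_csv(out / "truth.tsv", sep="\t")
    snp_paths = {}
    for hybrid, snps in study["snps"].items():
        path = out / f"snps_{hybrid}.tsv"
        ase_mod.write_snp_counts(snps, path)
        snp_paths[hybrid] = str(path)
        study["ase_truth"][hybrid].to_csv(out / f"ase_truth_{hybrid}.tsv", sep="\t")
    study["traits"].to_csv(out / "traits.tsv", sep="\t", index=False)
    study["annotations"].to_csv(out / "annotations.tsv", sep="\t", index=False)
    names = study["genotypes"]
    run_config = RunConfig(
        counts=str(out / "counts.tsv"),
        design=str(out / "design.tsv"),
        triads=[
            TriadSpec("test", names["line1"], names["tester"], names["hybrid1"]),
            TriadSpec("check", names["line2"], names["tester"], names["hybrid2"]),
        ],
        snps=snp_paths,
        traits=str(out / "traits.tsv"),
        annotations=str(out / "annotations.tsv"),
        outdir=str(out / "results"),
        seed=config.seed,
    )
    run_config.to_yaml(out / "config.yaml")
    return run_config
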