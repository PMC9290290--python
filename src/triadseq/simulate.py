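"""Seeded generators for triad count matrices, SNP allele counts and traits.

The generator emulates the study design the package targets: near-isogenic
parent lines crossed to a common tester, RNA-seq in triplicate, and hybrids
whose per-gene expression follows a configured pattern class relative to the
mid-parent value.  Gene baseline expression is log-normal; counts are drawn
from a negative binomial with a single shared dispersion (variance
m + dispersion * m^2; dispersion 0 gives Poisson, i.e. technical sampling
only).  Every draw is fixed by the config seed, and a truth table records
each gene's class, means and allelic fraction so recovery can be scored.

Class semantics (fold = ``fold_change``, pfc = ``parental_fold_change``):

    additive          parents differ by pfc; hybrid at the mid-parent value
    over_dominant     hybrid = fold * max(parents)
    under_dominant    hybrid = min(parents) / fold
    parent1_dominant  parent2 shifted by pfc; hybrid equals parent1
    parent2_dominant  parent1 shifted by pfc; hybrid equals parent2
    conserved         parents differ by pfc; hybrid at the 25% or 75% point
                      between them (off-midparent but inside the range)
    (remainder)       equal expression in all three genotypes
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import ValidationError
from .ase import SNP_COLUMNS
from .expression import CountMatrix, SampleDesign

DEFAULT_FRACTIONS: Mapping[str, float] = {
    "additive": 0.5,
    "over_dominant": 0.1,
    "under_dominant": 0.1,
    "parent1_dominant": 0.1,
    "parent2_dominant": 0.1,
    "conserved": 0.1,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the triad design the package models: 2000 genes, three
    replicates per genotype, one million fragments per library, log-normal
    baseline expression (sigma 1), negative-binomial dispersion 0.05, and
    the ASE substrate of four SNPs per gene at 50 reads each with allelic
    fractions 0.2 / 0.8 for the 20% of genes simulated as allelically biased.
    """

    n_genes: int = 2000
    replicates: int = 3
    depth: int = 1_000_000
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 1.0
    dispersion: float = 0.05
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    fold_change: float = 2.0
    parental_fold_change: float = 2.0
    gene_length_range: tuple[int, int] = (500, 5000)
    # ASE substrate
    n_genes_ase: int = 1000
    ase_fraction: float = 0.2
    allelic_fractions: tuple[float, ...] = (0.2, 0.8)
    snps_per_gene: int = 4
    reads_per_snp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(DEFAULT_FRACTIONS)
        if unknown:
            raise ValidationError(f"unknown pattern classes {sorted(unknown)}")
        fracs = np.array(list(self.class_fractions.values()), dtype=float)
        if (fracs < 0).any() or fracs.sum() > 1 + 1e-9:
            raise ValidationError("class fractions must be >= 0 and sum to <= 1")
        if self.fold_change <= 1 or self.parental_fold_change <= 1:
            raise ValidationError("fold changes must exceed 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.ase_fraction <= 1:
            raise ValidationError("ase_fraction must lie in [0, 1]")
        for f in self.allelic_fractions:
            if not 0 < f < 1:
                raise ValidationError("allelic fractions must lie in (0, 1)")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _assign_classes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    n = config.n_genes
    labels: list[str] = []
    for cls, frac in config.class_fractions.items():
        labels.extend([cls] * int(round(frac * n)))
    labels = labels[:n]
    labels.extend(["equal"] * (n - len(labels)))
    return rng.permutation(np.array(labels, dtype=object))


def _triad_means(
    rng: np.random.Generator, config: SimConfig, classes: np.ndarray
) -> pd.DataFrame:
    """Relative expression profiles (summing to 1 per parent) for a triad.

    Class semantics are defined on the relative scale — the scale on which
    FPKM-style comparisons actually operate — so that e.g. an "additive" gene
    sits exactly at the mean of the parents' relative abundances.  The hybrid
    profile is returned unnormalised (its sum deviates from 1 by a single
    global factor); per-sample count sampling renormalises it, and the
    classifier's ratio normalisation removes exactly that uniform factor.
    """
    base = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sigma, size=len(classes)
    )
    fc, pfc = config.fold_change, config.parental_fold_change
    sign = rng.choice([1.0, -1.0], size=len(classes))  # which parent sits higher
    m1 = base.copy()
    m2 = base.copy()
    for i, cls in enumerate(classes):
        shift = pfc if sign[i] > 0 else 1.0 / pfc
        if cls in ("additive", "parent1_dominant", "conserved"):
            m2[i] = base[i] * shift
        elif cls == "parent2_dominant":
            m1[i] = base[i] * shift
    q1 = m1 / m1.sum()
    q2 = m2 / m2.sum()
    f1 = (q1 + q2) / 2.0  # additive / equal default
    for i, cls in enumerate(classes):
        if cls == "over_dominant":
            f1[i] = fc * max(q1[i], q2[i])
        elif cls == "under_dominant":
            f1[i] = min(q1[i], q2[i]) / fc
        elif cls == "parent1_dominant":
            f1[i] = q1[i]
        elif cls == "parent2_dominant":
            f1[i] = q2[i]
        elif cls == "conserved":
            t = 0.25 if rng.random() < 0.5 else 0.75
            f1[i] = q1[i] + t * (q2[i] - q1[i])
    return pd.DataFrame({"mean_p1": q1, "mean_p2": q2, "mean_f1": f1})


def _sample_block(
    rng: np.random.Generator,
    means: np.ndarray,
    config: SimConfig,
    genotype: str,
) -> pd.DataFrame:
    props = means / means.sum()
    expected = config.depth * props
    cols = {}
    for r in range(1, config.replicates + 1):
        cols[f"{genotype}_r{r}"] = _nb_counts(rng, expected, config.dispersion)
    return pd.DataFrame(cols)


def _design_rows(genotype: str, role: str, replicates: int) -> list[dict]:
    return [
        {
            "sample_id": f"{genotype}_r{r}",
            "genotype": genotype,
            "role": role,
            "replicate": r,
        }
        for r in range(1, replicates + 1)
    ]


def simulate_triad(
    config: SimConfig,
    genotypes: tuple[str, str, str] = ("P1", "P2", "F1"),
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """One parent-parent-hybrid triad with known per-gene pattern classes.

    Returns (counts, design, truth); truth columns are class, mean_p1,
    mean_p2, mean_f1 indexed by gene id.  Identical configs (including seed)
    give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(rng, config)
    means = _triad_means(rng, config, classes)
    gene_ids = pd.Index(
        [f"gene{i:05d}" for i in range(config.n_genes)], name="gene_id"
    )
    lengths = pd.Series(
        rng.integers(*config.gene_length_range, size=config.n_genes),
        index=gene_ids, name="gene_length_bp",
    )
    p1, p2, f1 = genotypes
    blocks = [
        _sample_block(rng, means["mean_p1"].to_numpy(), config, p1),
        _sample_block(rng, means["mean_p2"].to_numpy(), config, p2),
        _sample_block(rng, means["mean_f1"].to_numpy(), config, f1),
    ]
    counts = pd.concat(blocks, axis=1)
    counts.index = gene_ids
    design = SampleDesign(
        pd.DataFrame(
            _design_rows(p1, "parent1", config.replicates)
            + _design_rows(p2, "parent2", config.replicates)
            + _design_rows(f1, "hybrid", config.replicates)
        ).set_index("sample_id")
    )
    truth = means.copy()
    truth.insert(0, "class", classes)
    truth.index = gene_ids
    return CountMatrix(counts, lengths), design, truth


def simulate_two_group(
    n_genes: int = 2000,
    frac_de: float = 0.1,
    fold: float = 4.0,
    replicates: int = 3,
    depth: int = 1_000_000,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Two genotypes, a fraction of genes shifted by ``fold`` with random sign.

    Truth columns: de (bool), direction ("up" = higher in group B, "down",
    or "ns").  Substrate for differential-expression recall/sign checks.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    n_de = int(round(frac_de * n_genes))
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[rng.permutation(n_genes)[:n_de]] = True
    up = rng.choice([True, False], size=n_genes)
    mean_b = base.copy()
    mean_b[de_mask & up] *= fold
    mean_b[de_mask & ~up] /= fold
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    lengths = pd.Series(
        rng.integers(500, 5000, size=n_genes), index=gene_ids, name="gene_length_bp"
    )
    config = SimConfig(
        n_genes=n_genes, replicates=replicates, depth=depth, dispersion=dispersion
    )
    blocks = [
        _sample_block(rng, base, config, "A"),
        _sample_block(rng, mean_b, config, "B"),
    ]
    counts = pd.concat(blocks, axis=1)
    counts.index = gene_ids
    design = SampleDesign(
        pd.DataFrame(
            _design_rows("A", "other", replicates)
            + _design_rows("B", "other", replicates)
        ).set_index("sample_id")
    )
    truth = pd.DataFrame(
        {
            "de": de_mask,
            "direction": np.where(de_mask, np.where(up, "up", "down"), "ns"),
            "mean_a": base,
            "mean_b": mean_b,
        },
        index=gene_ids,
    )
    return CountMatrix(counts, lengths), design, truth


# ---------------------------------------------------------------------------
# ASE
# ---------------------------------------------------------------------------

def simulate_ase(
    config: SimConfig, hybrid_id: str = "H1", gene_ids: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP allele counts for one hybrid with known allelic fractions.

    Each of ``n_genes_ase`` genes (ids supplied via ``gene_ids`` or generated)
    carries ``snps_per_gene`` SNPs with ``reads_per_snp`` total reads;
    allele-1 reads are binomial with the gene's true fraction f (f = 0.5 for
    non-ASE genes).
    """
    rng = np.random.default_rng(config.seed + 1)
    if gene_ids is None:
        gene_ids = [f"ase_gene{i:05d}" for i in range(config.n_genes_ase)]
    else:
        gene_ids = list(gene_ids)
    n = len(gene_ids)
    n_ase = int(round(config.ase_fraction * n))
    is_ase = np.zeros(n, dtype=bool)
    is_ase[rng.permutation(n)[:n_ase]] = True
    f = np.full(n, 0.5)
    f[is_ase] = rng.choice(config.allelic_fractions, size=n_ase)
    rows = []
    for i, g in enumerate(gene_ids):
        for s in range(config.snps_per_gene):
            k1 = int(rng.binomial(config.reads_per_snp, f[i]))
            rows.append(
                {
                    "hybrid_id": hybrid_id,
                    "chrom": "1",
                    "pos": i * 1000 + 10 * (s + 1),
                    "gene_id": g,
                    "reads_allele0": config.reads_per_snp - k1,
                    "reads_allele1": k1,
                }
            )
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    truth = pd.DataFrame(
        {"is_ase": is_ase, "allelic_fraction": f},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return snps, truth


# ---------------------------------------------------------------------------
# two-triad study, traits, annotations
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimConfig,
    line_diff_fraction: float = 0.05,
    genotypes: Mapping[str, str] | None = None,
) -> dict:
    """Two triads sharing a tester line (the full 15-sample study layout).

    Triad 1 (lineA x tester -> hyb1) follows the configured pattern classes;
    triad 2 (lineB x tester -> hyb2) is all-additive.  lineB deviates from
    lineA at a ``line_diff_fraction`` of genes (by the parental fold change),
    so the hyb1-vs-hyb2 DEG list can be partitioned against the lineA-vs-lineB
    list exactly as the pipeline does.  Returns a dict with counts, design,
    truth, snps (per hybrid), ase truths, traits and annotations.
    """
    names = {
        "tester": "tester", "line1": "lineA", "line2": "lineB",
        "hybrid1": "hyb1", "hybrid2": "hyb2",
    }
    if genotypes:
        names.update(genotypes)
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(rng, config)
    means1 = _triad_means(rng, config, classes)  # parent1=lineA, parent2=tester
    line_a = means1["mean_p1"].to_numpy()
    tester = means1["mean_p2"].to_numpy()
    hyb1 = means1["mean_f1"].to_numpy()

    n = config.n_genes
    line_diff = np.zeros(n, dtype=bool)
    line_diff[rng.permutation(n)[: int(round(line_diff_fraction * n))]] = True
    shift = np.where(
        rng.choice([True, False], size=n),
        config.parental_fold_change, 1.0 / config.parental_fold_change,
    )
    line_b = np.where(line_diff, line_a * shift, line_a)
    line_b = line_b / line_b.sum() * line_a.sum()  # keep relative scale comparable
    hyb2 = (line_b + tester) / 2.0  # all-additive control triad

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    lengths = pd.Series(
        rng.integers(*config.gene_length_range, size=n),
        index=gene_ids, name="gene_length_bp",
    )
    blocks, design_rows = [], []
    for label_key, mean, role in [
        ("tester", tester, "parent2"),
        ("line1", line_a, "parent1"),
        ("line2", line_b, "parent1"),
        ("hybrid1", hyb1, "hybrid"),
        ("hybrid2", hyb2, "hybrid"),
    ]:
        g = names[label_key]
        blocks.append(_sample_block(rng, mean, config, g))
        design_rows.extend(_design_rows(g, role, config.replicates))
    counts = pd.concat(blocks, axis=1)
    counts.index = gene_ids
    design = SampleDesign(pd.DataFrame(design_rows).set_index("sample_id"))
    truth = pd.DataFrame(
        {
            "class_hybrid1": classes,
            "line_diff": line_diff,
            "mean_tester": tester,
            "mean_line1": line_a,
            "mean_line2": line_b,
            "mean_hybrid1": hyb1,
            "mean_hybrid2": hyb2,
        },
        index=gene_ids,
    )

    ase_universe = list(
        gene_ids[np.sort(rng.permutation(n)[: min(config.n_genes_ase, n)])]
    )
    snps1, ase_truth1 = simulate_ase(
        config, hybrid_id=names["hybrid1"], gene_ids=ase_universe
    )
    cfg2 = SimConfig(**{**asdict(config), "seed": config.seed + 101})
    snps2, ase_truth2 = simulate_ase(
        cfg2, hybrid_id=names["hybrid2"], gene_ids=ase_universe
    )

    traits = simulate_traits(
        seed=config.seed + 7, hybrid=names["hybrid1"], check=names["hybrid2"]
    )
    annotations = simulate_annotations(gene_ids, seed=config.seed + 11)
    return {
        "counts": CountMatrix(counts, lengths),
        "design": design,
        "truth": truth,
        "snps": {names["hybrid1"]: snps1, names["hybrid2"]: snps2},
        "ase_truth": {names["hybrid1"]: ase_truth1, names["hybrid2"]: ase_truth2},
        "traits": traits,
        "annotations": annotations,
        "genotypes": names,
    }


def simulate_traits(
    seed: int = 0,
    hybrid: str = "hyb1",
    check: str = "hyb2",
    trait: str = "ear_width_mm",
    environments: int = 3,
    check_mean: float = 50.0,
    effect: float = 0.05,
    sd: float = 1.2,
    n: int = 10,
) -> pd.DataFrame:
    """Summary trait rows for a test and check hybrid across environments."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(1, environments + 1):
        env = f"E{e}"
        c = check_mean + rng.normal(0, sd)
        h = check_mean * (1 + effect) + rng.normal(0, sd)
        rows.append(
            {"trait": trait, "environment": env, "genotype": check,
             "mean": round(c, 2), "sd": sd, "n": n}
        )
        rows.append(
            {"trait": trait, "environment": env, "genotype": hybrid,
             "mean": round(h, 2), "sd": sd, "n": n}
        )
    return pd.DataFrame(rows)


def simulate_annotations(
    gene_ids: Iterable[str],
    n_terms: int = 25,
    mean_term_size: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Random flat gene-to-term annotations over the given gene universe."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(list(gene_ids))
    rows = []
    cats = ["BP", "MF", "CC"]
    for t in range(n_terms):
        size = max(2, rng.poisson(mean_term_size))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        term = f"TERM:{t:04d}"
        cat = cats[t % len(cats)]
        rows.extend(
            {"gene_id": g, "term_id": term, "term_name": f"synthetic term {t}",
             "category": cat}
            for g in members
        )
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "category"])


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Confusion matrix plus per-class precision/recall and overall accuracy."""

    confusion: pd.DataFrame  # rows: truth; columns: call
    per_class: pd.DataFrame  # precision, recall indexed by class
    accuracy: float
    n_ambiguous: int


def evaluate_recovery(calls: pd.Series, truth: pd.Series) -> RecoveryReport:
    """Score pattern (or any categorical) calls against simulator truth."""
    if set(calls.index) != set(truth.index):
        raise ValidationError("calls and truth cover different gene universes")
    calls = calls.reindex(truth.index)
    confusion = pd.crosstab(truth, calls, dropna=False)
    classes = sorted(set(truth) | set(calls))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    rows = []
    for cls in classes:
        tp = int(((calls == cls) & (truth == cls)).sum())
        n_called = int((calls == cls).sum())
        n_true = int((truth == cls).sum())
        rows.append(
            {
                "class": cls,
                "precision": tp / n_called if n_called else np.nan,
                "recall": tp / n_true if n_true else np.nan,
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    return RecoveryReport(
        confusion=confusion,
        per_class=per_class,
        accuracy=float((calls == truth).mean()),
        n_ambiguous=int((calls == "ambiguous").sum()),
    )
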