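# Methods

## Expression measurement and filters

Raw fragment counts per gene and sample are normalised to FPKM,
`1e9 * count / (gene_length_bp * library_size)`, with library sizes taken as
column sums of the count matrix unless supplied (total aligned-fragment
counts are not recoverable from a count table alone).  A gene counts as
*expressed* in a genotype when its mean FPKM across that genotype's
replicates reaches 1; a flag switches to the laxer any-replicate rule, since
published threshold statements rarely specify replicate handling.  Expressed
genes are binned as high (≥ 50 FPKM), medium ([20, 50)) and low ([1, 20)),
with left-closed boundaries so a gene at exactly 50 is "high".

## Exact tests

All between-genotype comparisons use a two-sided Fisher exact test on the
2×2 table of (gene count, library remainder) for the two pooled profiles.
Two-sided p-values follow the probability-ordering convention (total mass of
outcomes no more probable than the observed one), which differs from
doubling the smaller tail; the same convention applies to the exact binomial
test used per SNP, where a mid-p variant is available behind a flag.
BH (step-up) and BY (step-up with the harmonic-sum factor, valid under
arbitrary dependence) adjustments are applied per comparison family.
Trait means are compared with Welch's unequal-variance t test from summary
statistics (a pooled Student variant is a flag), since published trait
tables rarely name the test; with both variances zero, equality of means
decides the outcome.

## Composition-corrected libraries

Sequencing measures *relative* abundance: if one group of genes rises, the
apparent rates of every other gene in that library fall.  A Fisher test on
raw library sums would therefore flag unchanged genes whenever the
transcriptome's composition shifts.  By default each pairwise comparison
rescales one library by the median per-gene rate ratio over all genes
observed in both profiles (median-of-ratios, in the spirit of DESeq size
factors / TMM), centring the typical gene's ratio at 1 before testing.
`normalization="library"` restores the raw behaviour.  The correction is a
single global factor and so cannot hide genuinely per-gene effects, but it
does mean a *uniform* amplification of every transcript is — necessarily —
invisible, as in any relative quantification.

## Differential expression and set partitioning

Genes expressed in at least one of the two genotypes are tested (keeping the
BH denominator meaningful); replicates are pooled before the exact test, so
biological replicate-to-replicate dispersion is not modelled — a Welch t
test on log2(FPKM + 1) across replicates is available as a dispersion-aware
alternative.  Log2 fold changes use a 1-FPKM pseudocount.  The set-partition
operation splits a primary DEG list by membership in a secondary comparison
(shared vs unique); membership alone decides sharing — no direction
agreement is required, as the direction convention between two different
comparisons is not well defined.

## Pattern classification

The mid-parent value is materialised as a pseudo-sample — per-gene counts
are the half-up-rounded means of the parents' pooled counts, the library the
mean of the pooled libraries — so the identical exact test serves F1-vs-MPV
and F1-vs-parent comparisons.  Each of the three comparisons is BH-adjusted
as its own family.  The decision tree: non-significant vs MPV → additive;
otherwise over-/under-dominant when significant vs both parents and above/
below both; otherwise parent-dominant when indistinguishable from exactly
one parent; otherwise conserved when significant vs both parents yet
strictly inside the parental range (endpoints excluded); anything else —
e.g. indistinguishable from both parents while differing from their mean —
is ambiguous.  The precedence order (over/under-dominance before
single-parent dominance before conserved) is a package choice: published
class taxonomies rarely order their rules, and real data produce genes
satisfying none.

## ASE calling

Per SNP, the allele-1 read count is tested against Binomial(total, 0.5);
the BH family is all testable SNPs of one hybrid.  Gene-level P is the
read-weighted mean of SNP-level P (robust to shallow SNPs, degenerating to
the single-SNP value), with a pooled-read-ratio mode as an alternative since
aggregation conventions differ between pipelines.  The strict rule calls a
gene ASE when ≥ 2 significant SNPs lie on the same side of 0.5 and gene P is
outside [0.4, 0.6]; the relaxed rule instead requires ≥ 2 testable SNPs plus
a significant pooled-read binomial test.  SNPs with zero reads are excluded
from the analysed denominator; upstream SNP-discovery filters (unique
mapping, parental consensus) are assumed already applied, and the validator
rejects duplicated positions or positions mapped to multiple genes.

## Phenotype indices

Over-standard heterosis is computed against a configurable check genotype
and reported at 2 decimals; across-environment averages are means of the
per-environment percentages (not the percentage of averaged means), matching
how such tables are printed.  The degree of dominance uses
d = F1 − midparent, a = half the absolute parental difference; it is
invariant under parent relabelling, and a = 0 (coincident parents) flags the
ratio as undefined with the mode decided by the sign of d alone.

## Enrichment

Terms are scored with the hypergeometric upper tail P(X ≥ k) against a
declared population (defaulting, in the pipeline, to the expressed-gene
universe of the test hybrid rather than the whole genome), BY-adjusted by
default because overlapping terms are strongly dependent.  The annotation
table is taken as already propagated; no ontology-graph rollup is performed.

## Synthetic data

The generator emulates the targeted study design: near-isogenic parent
lines, a common tester, three replicates per genotype, ~10⁶ fragments per
library.  Baseline expression is log-normal (σ = 1); counts are negative
binomial with one shared dispersion (variance m + φm², default φ = 0.05 as a
modest value for isogenic triplicates; φ = 0 gives pure multinomial/Poisson
sampling).  Class fractions default to 50% additive and 10% for each
non-additive class, with any remainder as equal-expression genes; effect
sizes default to 2-fold.  ASE tables default to 1000 genes × 4 SNPs × 50
reads with 20% of genes biased at allelic fractions 0.2/0.8.

Class semantics are defined on the **relative-abundance scale** — the scale
FPKM comparisons observe: an additive gene's hybrid relative abundance is
exactly the mean of the parents' relative abundances, a parent-dominant
gene's equals that parent's, the conserved class sits at the 25% or 75%
point between the parents (guaranteeing separation from both the MPV and the
parents).  Defining the classes on absolute means instead would make the
additive null unattainable for any relative-measurement method, because the
two parents' differing compositions displace the absolute-mean MPV from the
FPKM-space MPV.

What the generator does *not* emulate: GC/length biases, batch effects,
isoform switching, mapping artefacts, or gene-specific dispersions.  Passing
calibration and recovery tests therefore demonstrates correctness of the
statistical machinery under the stated sampling model, not robustness to
every artefact of real libraries.

## Calibration and recovery experiments

The null-calibration experiments (all-additive triads; balanced allelic
fractions) and the recovery experiment run at dispersion 0, because the
pooled-count exact test models sampling noise only; with biological
overdispersion the test is anticonservative, which is a known cost of
pooling replicates into a Poisson-like test and is documented here as a
limitation (the Welch alternative exists for dispersion-aware calls).
The recovery experiment uses 2500 genes — five non-additive classes of 400
genes each (the evaluated set) on a 500-gene equal-expression background —
at 4-fold effects.  The background is part of the design: a transcriptome in
which literally every gene changed leaves no anchor for any normalisation,
making the composition scale unidentifiable.  Four-fold effects are the
package's strong-effect regime, chosen so each pairwise test is decisive
across the whole log-normal abundance range.  Measured under these
conditions: pattern null FPR ≈ 0 (≤ 0.05), recovery accuracy 0.92–0.94,
ASE precision and recall 1.0, ASE null FPR ≈ 0, DEG recall 1.0 with exact
sign agreement (see `scripts/acceptance.py`).

The gene-level allelic-fraction estimate is a binomial proportion over
(SNPs × reads) ≈ 200 reads; its accuracy is checked against its exact
sampling law — e.g. P(|P̂ − 0.8| ≤ 0.05) = 0.937 at 200 reads — rather than
against an arbitrary coverage target.

## Numerical conventions

Half-up rounding for pseudo-counts and all printed percentages (2 dp);
all-zero Fisher tables return p = 1 with a warning; empty expression-bin
input yields undefined (None) fractions rather than division errors; the
log2 fold-change pseudocount (1 FPKM) is recorded on the results object.
Every simulator draw derives from a single integer seed; identical configs
give byte-identical outputs.

## Known limitations

Pooling replicates discards biological dispersion (anticonservative under
overdispersion); uniform transcriptome-wide amplification is invisible to
relative quantification; the MPV pseudo-sample halves the variance the
Fisher test assumes for it (making F1-vs-MPV slightly conservative); ASE
calling assumes pre-filtered SNP tables and does not phase or decompose
cis/trans effects.
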