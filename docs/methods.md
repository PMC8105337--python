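# Methods

`myelotrace` implements the bespoke computational procedures of a
longitudinal multi-omics analysis of multiple myeloma: mapping somatic
mutations to single cells through droplet barcodes, placing somatic
mutations on germline haplotypes with linked reads, genotype-threshold
ancestry inference with reference-panel PCA projection, ordered
copy-number categorization, and tracking of plasma-cell subpopulations
across disease timepoints. Every stage is exercisable on synthetic data
with known truth; this note records the models, the parameters that
matter, and the design choices made where the procedures were
underdetermined.

## Synthetic data model (`syndata`)

The generators are pure functions of their parameters and a seed
(NumPy `default_rng`); repeated calls are byte-identical, including the
SAM text stream.

**Clonal architecture.** A subclone tree in which the root clone has
cancer-cell fraction (CCF) 1.0 at every timepoint and each child draws
a random share of its parent's unallocated CCF, guaranteeing that
sibling CCFs sum to at most the parent's. Cells (and linked-read
molecules) are assigned to tree nodes with probability equal to the
node's occupancy (its CCF minus its children's), scaled by per-timepoint
tumor purity; non-tumor cells carry no somatic variants and are copy
neutral. Every variant belongs to exactly one subclone and one germline
haplotype; each non-root subclone perturbs one chromosome's copy ratio
(0.5 / 1.5 / 2.0) on top of its parent's profile so subclones are
separable in copy-number space.

**Tagged reads.** Single-end 100 bp reads, perfectly aligned (100M)
except for the base at the variant locus; per cell and locus the read
count is Poisson(`mean_depth`, default 20), one read per UMI. A read
shows the alternate base iff the cell's lineage carries the variant,
flipped with probability `error_rate` (default 0.01). Cell barcodes and
UMIs use the common two-letter droplet tags (`CB`/`UB`, configurable)
and are collision-free by construction (base-4 index encoding).
Realistic sequencing error profiles, mappability, doublets and ambient
RNA are deliberately out of scope: the pipeline consumes alignments,
not raw reads, so tests on these data show correctness of the counting
logic, not robustness to alignment artifacts.

**Linked reads.** Fixed-length molecules (default 50 kb; the length and
depth distributions of real linked-read libraries are not modeled —
conventional values, not inferred ones) with uniform starts over the
region around the chosen somatic sites, a uniform haplotype, and a
source clone drawn like a cell. Molecules report the haplotype allele
at every phased het they span and the somatic alternate iff lineage
and haplotype both match; each observation flips with `error_rate`.
Barcode collisions within a window are not modeled; distant collisions
are handled downstream by gap splitting.

**Genotype panel.** Balding–Nichols: ancestral frequencies
Uniform(0.05, 0.95) (emulating a common-variant marker set), population
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence `fst`,
Hardy–Weinberg genotypes, Poisson(30) depth, Binomial(depth, dosage/2)
alternate counts, and a 2% default missing rate. `fst = 0` collapses to
exchangeable populations and is used as a negative control against
label leakage.

**Expression counts.** Negative binomial (dispersion r = 2) around
lognormal per-gene means scaled by lognormal library-size factors
(sd 0.3); planted programs multiply their genes by a fold in designated
clusters. The two-timepoint tracking scenario plants subpopulations A
(stable, own program, chr13 loss), B (lost, own program, neutral) and a
relapse-emergent C (gained, own program, chr13 deletion + chr16 gain);
newly dominant subclones are given multiple copy-number alterations, as
relapse subpopulations in this disease typically differ from
pre-existing ones at several chromosomes.

## Somatic call consensus and filters (`varfilter`)

SNVs are retained when reported by ≥2 of {Mutect, VarScan, Strelka},
INDELs by ≥2 of {VarScan, Strelka, Pindel}; merged records carry the
union of caller ids and the per-field maximum of depths and VAFs across
callers (union-with-max keeps the strongest evidence seen by any
caller; this is the package's reconciliation rule). The somatic
hard filter keeps calls with tumor depth ≥ 14, normal depth ≥ 8, tumor
VAF ≥ 0.05 and normal VAF ≤ 0.02 — retention is inclusive at the stated
values, following the convention that "a cutoff of X" admits X.
Structural variants need somatic score ≥ 30 and junction somatic
score ≥ 30. Sample identity across timepoints is checked by Pearson
correlation of germline VAFs over a small panel of germline loci (two
dozen suffice): pairs with r ≥ 0.8 over ≥ 5 shared loci are flagged
same-patient; both constants are this package's formalization, chosen
because simulation shows identical-genotype pairs and unrelated pairs
separate by a wide margin at these values.

## Per-cell mutation mapping (`scmap`)

A read contributes one observation per covered SNV when its alignment
places an aligned (non-gap, non-clipped) base at the position, with
MAPQ ≥ 10 (default); unmapped, secondary/supplementary and
duplicate-flagged reads are skipped and tallied. Within each
(cell, variant, UMI) the consensus allele is the read majority, ties
discarding the UMI; a cell is "alt-detected" at a variant with ≥ 1
alt UMI, "ref-only" with only reference UMIs. The group single-cell VAF
is defined at the cell level — alt-detected cells over covered cells —
with the UMI-level fraction emitted as a secondary column so either
denominator convention is available. Indels are
excluded (they would require realignment logic the counting tool does
not attempt); base-quality filtering is not applied. Coordinates are
1-based in VCF/SAM inputs, 0-based half-open internally.

## Haplotype phasing of somatic pairs (`linkphase`)

Observations sharing a barcode and chromosome chain into one molecule
while consecutive positions are ≤ 50 kb apart (`max_gap_bp`). Each
alt-carrying molecule votes for the haplotype matching the majority of
its covered phased hets; the variant is assigned to the majority
haplotype when votes ≥ 2 (`min_votes`) and the winning fraction ≥ 0.8
(`purity_thresh`), else ambiguous. For a somatic pair, one both-alt
molecule (configurable, `min_cis_molecules`) forces "cis"; otherwise
"independent" requires each alternate to appear among the both-covering
molecules and ≥ 3 such molecules (`min_cover`): a floor of 2 would be
fragile to a single chimeric barcode, while verdicts of this kind are
realistically drawn from a handful (around four) of covering
molecules.

## Ancestry (`ancestry`)

Genotype calls from allele read counts: hom-ref if ref ≥ 8 and alt < 4;
het if ref ≥ 4 and alt ≥ 4; hom-alt if ref < 4 and alt ≥ 8; missing
otherwise (the three rules are disjoint, so the mapping is total).
Markers missing in > 5% of samples are dropped. Reference dosages are
imputed at the per-marker mean, centered and scaled to unit variance
(sd floor 1e−8; standardization is the conventional choice for
genotype PCA and is recorded here so coordinates are comparable); the
top 20 principal
components feed a 500-tree random forest evaluated on a stratified
80/20 split. Queries are standardized with the reference statistics and
projected through the stored loadings — the PCA is never refit — making
projection an affine map (verified by a convex-combination property
test). Accuracies achievable on real continental reference panels are
properties of those panels and are not synthetic targets; the
synthetic criterion is ≥ 0.99 held-out accuracy on a
3-population, 200-per-population, 2000-marker, Fst 0.1 panel and
chance-level accuracy at Fst 0.

## Copy-number categories and subclustering (`cnvcat`)

Log2 copy ratios map to deletion < loss < neutral < gain <
amplification with cutoffs (−1, −0.25, 0.2, 0.7) for bulk platforms and
(−1, −0.4, 0.3, 0.7) for scRNA inference (whose relative intensities
are first log2-transformed, non-positive values clipped to 1e−3 and the
result clipped to ±3). Boundary values belong to the higher category
(the package's convention, recoverable by bisection to 1e−6). The
chromosome-deletion flag is strict: mean relative copy value < 0.76 on
the linear scale where neutral = 1 (the relative-ratio scale, so the
flag is purity- and ploidy-agnostic).

Subclustering runs DBSCAN on the top 10 principal components of the
CNV gene panel over a grid of eps (20 log-spaced values spanning the
5th–95th percentile of pairwise distances) and minPts {5, 10, 15, 20}.
The selected grid point maximizes the mean silhouette over non-noise
points **multiplied by the fraction of cells assigned**: the raw
non-noise silhouette is degenerate under DBSCAN — it rewards tiny dense
cores that label most cells noise — and the weighting restores the
intended behavior (exact recovery of separable groups) while remaining
a silhouette-based grid search. Ties break toward larger eps, then
larger minPts. Clustering is done in PCA space rather than a stochastic
2-D embedding so the result is deterministic.

## Subpopulations (`subpop`)

Counts are normalized to 10,000 per cell and log1p-transformed.
Differential expression is the Wilcoxon rank-sum test (cluster vs rest)
with Benjamini–Hochberg adjustment; subcluster mode keeps fold
change > 1.5 and FDR < 0.1 (strict inequalities), marker
mode keeps adjusted p < 0.05 with positive log fold change. Fold change
is the ratio of expm1 of cluster means of log-normalized values with a
1e−9 pseudo-count (the estimator used by `scanpy.tl.rank_genes_groups`,
which performs the test). Pathway overrepresentation is the upper-tail
hypergeometric test against the expressed-gene universe with BH
adjustment — an explicit reimplementation of the overrepresentation
idea, not a wrapper around an annotation-database package.
Subpopulations are grouped by Pearson correlation of −log10 q over
pathways significant (q < 0.05) in at least one subpopulation, then
average-linkage hierarchical clustering on 1 − r (average linkage and
correlation distance are this package's choices; any agglomerative
scheme over the correlation matrix fits the procedure).

Cross-timepoint matching scores each pair as 0.5 × Pearson(centroids
over the shared variable-gene panel) + 0.5 × (fraction of chromosomes
with concordant CNV category), greedily accepts pairs in decreasing
similarity one-to-one, and stops below 0.6. Matched subpopulations are
stable; unmatched ones are gained (later timepoint) or lost (earlier).
This rule is a deterministic stand-in for the visual co-clustering of
integrated embeddings that analysts otherwise rely on; all three
constants are configuration, not empirical estimates. Swapping the two
timepoints maps gained ↔ lost and preserves stable.

The QC check splits cells at 1000 expressed genes and compares a gene
program's mean expression across cell types within each stratum, with a
Mann–Whitney statistic per cell type between strata; a program that is
genuinely biological should be elevated in its cell type in both
strata.

## Problem sizes and tolerances

The test suite and the acceptance script use: 50 cells × 9 variants at
15× depth for exact per-cell recovery (noiseless); 500 replicates of
80 molecules at 1% error for haplotype recovery (criterion ≥ 99%);
600 samples × 2000 markers (Fst 0.1) for ancestry (criterion ≥ 0.99
held-out accuracy; chance at Fst 0); 300 cells, 3 subclones, noise
sd 0.1 for subclustering (criterion ARI ≥ 0.9); 600 cells × 800 genes
with a 100-gene fold-3 program for DEG calling (sensitivity ≥ 0.9,
FDR ≤ 0.1); and 25 replicates of the 600-cell two-timepoint scenario
for tracking (criterion ≥ 95% exact pattern + pathway recovery). These
sizes were chosen as the smallest at which the stochastic criteria are
statistically comfortable, keeping the full suite around a minute of
compute.

## Known limitations

- The synthetic alignments contain no mismatches besides the variant
  base, so MAPQ/base-quality interactions are untested by construction.
- Molecule length is fixed rather than drawn from a fragment-size
  distribution; haplotype-recovery rates on real linked-read libraries
  will depend on the true length distribution and het density.
- The matching rule assumes subpopulation centroids are comparable
  across timepoints (shared gene panel, same normalization); batch
  effects between timepoints are not modeled.
- The five-category CNV scheme discards within-category magnitude;
  concordance-based matching is correspondingly coarse.
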