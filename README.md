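# myelotrace

Single-cell and linked-read analysis of clonal evolution in multiple
myeloma. The package implements, as a tested pipeline, the bespoke
procedures used to follow a tumor's subclonal architecture through
disease stages:

- **`scmap`** — map somatic SNVs to individual cells by tracing cell
  barcodes and UMIs through tagged alignments: per-cell ref/alt UMI
  counts, per-group single-cell VAFs, and within-cell mutation
  co-occurrence.
- **`linkphase`** — reconstruct barcode-defined DNA molecules from
  linked reads, assign somatic mutations to germline haplotypes by
  majority vote over phased heterozygous sites, and classify somatic
  mutation pairs as *cis* (same lineage) or *independent* subclones
  from their co-occurrence pattern on molecules covering both sites.
- **`varfilter`** — 2-of-3 caller consensus for somatic SNVs/INDELs,
  coverage/VAF hard filters (tumor ≥ 14×, normal ≥ 8×, tumor
  VAF ≥ 0.05, normal VAF ≤ 0.02), SV score filters (somatic and
  junction scores ≥ 30), and germline-VAF sample-identity checks.
- **`ancestry`** — threshold genotype calls from allele read counts
  (0/0: ref ≥ 8 & alt < 4; 0/1: ref ≥ 4 & alt ≥ 4; 1/1: ref < 4 &
  alt ≥ 8; else missing), marker vacancy filtering (> 5% dropped),
  reference-panel PCA (top 20 components), query projection with the
  reference statistics, and random-forest ancestry classification.
- **`cnvcat`** — ordered five-level copy-number categories
  (deletion < loss < neutral < gain < amplification) from log2 ratios
  with platform-specific cutoffs, chromosome-level deletion flags
  (CN < 0.76), and DBSCAN subclustering on a CNV gene panel with
  silhouette-selected parameters.
- **`subpop`** — Wilcoxon differential expression (fold change > 1.5,
  FDR < 0.1 for subclusters; adjusted p < 0.05 for markers),
  hypergeometric pathway overrepresentation, enrichment-correlation
  grouping of subpopulations, greedy cross-timepoint matching with
  stable/gained/lost calls, and an expressed-gene-count-stratified QC
  check.
- **`syndata`** — seeded generators for every input the pipeline
  consumes (tagged SAM, linked-read molecule tables, Balding–Nichols
  genotype panels, subclone CNV matrices, clustered expression counts
  with planted programs), each with a ground-truth table, so all
  stages are testable without access-restricted patient data.

The scientific core in brief: a subclone tree with per-timepoint
cancer-cell fractions assigns each tumor cell a lineage; a cell shows a
mutation's alternate allele iff its lineage carries it, so per-cell
allele counting recovers subclone membership. A somatic mutation sits
on haplotype *h* when molecules carrying its alternate allele match
haplotype *h* at surrounding phased hets; two mutations on the same
haplotype that never co-occur on molecules covering both sites arose in
independent subclones. See `docs/methods.md` for the full model,
parameter defaults, and design decisions.

## Worked example

Simulate a fully clonal three-subclone sample, map its somatic variants
back to cells, and summarize detection per subclone:

```python
from myelotrace import syndata, scmap

arch = syndata.gen_architecture(seed=7, n_subclones=3, n_timepoints=1,
                                n_variants=9, purity=[1.0])
header, reads, truth = syndata.gen_tagged_reads(
    arch, timepoint=0, n_cells=50, mean_depth=15, error_rate=0.0, seed=14)

obs, log = scmap.extract_observations(reads, arch.variants)
calls = scmap.collapse_umis(obs)
summary, _ = scmap.group_summary(
    calls, truth.rename(columns={"subclone": "group"}))
print(summary.head(6).to_string(index=False))
```

```
variant_id group  n_alt_cells  n_ref_only_cells  sc_vaf  umi_vaf
        v0   sc0           19                 0     1.0      1.0
        v0   sc1           10                 0     1.0      1.0
        v0   sc2           21                 0     1.0      1.0
        v1   sc0            0                19     0.0      0.0
        v1   sc1           10                 0     1.0      1.0
        v1   sc2           21                 0     1.0      1.0
```

`v0` is the truncal variant — every covered cell in every subclone is
alt-detected (single-cell VAF 1.0). `v1` belongs to the branch below
the root: it is detected in all covered `sc1`/`sc2` cells and in none
of the 19 covered root (`sc0`) cells, exactly the planted lineage
structure (6731 reads → 450 cell-variant calls).

Ancestry inference on a synthetic three-population panel:

```python
from myelotrace import ancestry

panel = syndata.gen_genotype_panel(n_pops=3, n_per_pop=200,
                                   n_markers=2000, fst=0.1, seed=11)
geno = ancestry.call_genotype_matrix(panel.ref, panel.alt)
kept = ancestry.filter_markers(geno)
model = ancestry.fit_projection(geno[kept], panel.populations,
                                n_components=20, seed=11)
print(f"{len(kept)} of {geno.shape[1]} markers retained; "
      f"held-out accuracy {model.holdout_accuracy:.3f}")
```

```
2000 of 2000 markers retained; held-out accuracy 1.000
```

A command-line interface mirrors the main stages
(`myelotrace simulate|scmap|somatic-filter|identity|ancestry|categorize|subcluster`);
run `myelotrace --help`.

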