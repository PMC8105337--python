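"""Plasma-cell subpopulation characterization and longitudinal tracking.

Subclusters of plasma cells within a sample are characterized by their
differentially expressed genes (Wilcoxon rank-sum vs the rest,
Benjamini–Hochberg correction; fold change > 1.5 and FDR < 0.1 in
subcluster mode, adjusted p < 0.05 in marker mode), their pathway
overrepresentation (upper-tail hypergeometric test against gene sets),
and their per-chromosome copy-number categories.  Subpopulations are
grouped across samples by the Pearson correlation of their -log10
enrichment q-value profiles over pathways significant in at least one
subpopulation, followed by average-linkage hierarchical clustering on
1 - r.  Across adjacent timepoints subpopulations are matched greedily
by a weighted combination of centroid expression correlation and
copy-number category concordance; matched subpopulations are "stable",
unmatched ones at the later timepoint "gained" and at the earlier
timepoint "lost".  A QC check stratifies cells by expressed-gene count
(default >= 1000 vs < 1000) and compares a gene program's expression
across cell types within each stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_log",
    "select_degs",
    "enrich_pathways",
    "enrichment_correlation_clusters",
    "celltype_sample_correlation",
    "SubpopulationProfile",
    "TrackingResult",
    "profiles_from_anndata",
    "match_subpopulations",
    "qc_stratified_check",
]


def normalize_log(adata, target_sum: float = 10_000.0):
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    Cells with zero total counts are dropped with a warning.  Returns a
    new AnnData; raw counts are kept in ``layers['counts']``.
    """
    import scanpy as sc

    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals == 0).any():
        warnings.warn(
            f"dropping {int((totals == 0).sum())} zero-count cell(s)",
            stacklevel=2,
        )
        adata = adata[totals > 0]
    adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def select_degs(
    adata,
    groupby: str,
    mode: str = "subcluster",
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.1,
    p_thresh: float = 0.05,
    min_cells: int = 3,
) -> dict[str, pd.DataFrame]:
    """Per-cluster differentially expressed genes (cluster vs rest).

    Uses the Wilcoxon rank-sum test on log-normalized values with
    Benjamini–Hochberg adjustment.  ``mode='subcluster'`` keeps genes
    with fold change > ``fc_thresh`` and FDR < ``fdr_thresh`` (the
    subcluster-resolving criterion); ``mode='marker'`` keeps genes with
    adjusted p < ``p_thresh`` and positive log fold change (the
    cell-type marker criterion).  Fold change is the ratio of expm1 of
    cluster means of the log-normalized values.  Returns a dict mapping
    cluster to a gene table sorted by q-value.
    """
    import scanpy as sc

    if mode not in ("subcluster", "marker"):
        raise ValueError(f"unknown mode {mode!r}")
    sizes = adata.obs[groupby].value_counts()
    small = sizes[sizes < min_cells]
    if len(small):
        raise ValueError(
            f"cluster(s) below {min_cells} cells: {list(small.index)}"
        )
    adata = adata.copy()
    adata.obs[groupby] = adata.obs[groupby].astype(str).astype("category")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            adata, groupby, method="wilcoxon", tie_correct=True,
            pts=False, n_genes=adata.n_vars,
        )
    out: dict[str, pd.DataFrame] = {}
    for cluster in adata.obs[groupby].cat.categories:
        df = sc.get.rank_genes_groups_df(adata, group=cluster)
        df = df.rename(
            columns={"names": "gene", "logfoldchanges": "log2fc",
                     "pvals": "pval", "pvals_adj": "qval"}
        )
        if mode == "subcluster":
            keep = (df["log2fc"] > np.log2(fc_thresh)) & (df["qval"] < fdr_thresh)
        else:
            keep = (df["qval"] < p_thresh) & (df["log2fc"] > 0)
        out[str(cluster)] = (
            df.loc[keep, ["gene", "log2fc", "pval", "qval"]]
            .sort_values("qval", kind="stable")
            .reset_index(drop=True)
        )
    return out


def enrich_pathways(
    deg_set: set[str],
    universe: set[str],
    pathway_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a DEG set in pathways.

    For each pathway (intersected with the universe), the upper-tail
    hypergeometric p-value of the observed overlap is computed, then
    Benjamini–Hochberg adjusted across pathways.  An empty DEG set
    yields q = 1 everywhere.
    """
    universe = set(universe)
    deg_set = set(deg_set) & universe
    n_universe = len(universe)
    rows = []
    for name, genes in pathway_sets.items():
        in_universe = set(genes) & universe
        overlap = len(deg_set & in_universe)
        if len(deg_set) == 0 or len(in_universe) == 0:
            p = 1.0
        else:
            p = float(
                stats.hypergeom.sf(
                    overlap - 1, n_universe, len(in_universe), len(deg_set)
                )
            )
        rows.append((name, len(in_universe), overlap, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["pathway", "pathway_size", "overlap", "pval"]
    )
    df["qval"] = multipletests(df["pval"], method="fdr_bh")[1] if len(df) else []
    return df


def enrichment_correlation_clusters(
    enrichment: pd.DataFrame,
    sig_thresh: float = 0.05,
    n_groups: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Group subpopulations by correlation of their enrichment profiles.

    ``enrichment`` is subpopulations x pathways of q-values.  Pathways
    significant (q < ``sig_thresh``) in at least one subpopulation are
    kept; q-values are transformed to -log10 and subpopulations are
    correlated pairwise (Pearson).  Subpopulations with a constant
    profile have undefined correlation and are excluded with a warning.
    Average-linkage hierarchical clustering on distance 1 - r is cut
    into ``n_groups`` groups.
    """
    if enrichment.shape[0] < 2:
        raise ValueError("need at least two subpopulations")
    sig = (enrichment < sig_thresh).any(axis=0)
    if not sig.any():
        raise ValueError("no significant pathways")
    x = -np.log10(enrichment.loc[:, sig].clip(lower=1e-300))
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"excluding constant enrichment profile(s): "
            f"{list(x.index[constant])}", stacklevel=2,
        )
        x = x.loc[~constant]
    corr = x.T.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=min(n_groups, len(x)), criterion="maxclust")
    return corr, pd.Series(labels, index=x.index, name="enrichment_group")


def celltype_sample_correlation(
    adata,
    cell_type_col: str = "cell_type",
    sample_col: str = "sample",
    p_thresh: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per cell type, sample-by-sample correlation of marker expression.

    Marker genes for each cell type are the significantly highly
    expressed genes versus the other types (adjusted p < 0.05 and
    positive log fold change); each sample is summarized by the mean
    log-normalized expression of those markers over its cells of that
    type, and samples are correlated pairwise (Pearson).  Samples
    lacking the cell type produce missing entries.
    """
    if adata.obs[sample_col].nunique() < 2:
        raise ValueError("need at least two samples")
    markers = select_degs(adata, cell_type_col, mode="marker",
                          p_thresh=p_thresh)
    out: dict[str, pd.DataFrame] = {}
    samples = list(pd.unique(adata.obs[sample_col]))
    for ct, table in markers.items():
        genes = [g for g in table["gene"] if g in adata.var_names]
        if not genes:
            continue
        sub = adata[adata.obs[cell_type_col].astype(str) == ct]
        profile = {}
        for s in samples:
            cells = sub[sub.obs[sample_col] == s]
            if cells.n_obs == 0:
                continue
            profile[s] = np.asarray(
                cells[:, genes].X.mean(axis=0)
            ).ravel()
        if len(profile) < 2:
            continue
        mat = pd.DataFrame(profile, index=genes)
        out[ct] = mat.corr(method="pearson").reindex(
            index=samples, columns=samples
        )
    return out


# ---------------------------------------------------------------------------
# longitudinal subpopulation tracking
# ---------------------------------------------------------------------------


@dataclass
class SubpopulationProfile:
    """Fingerprint of one sample subcluster.

    ``centroid`` is the mean log-normalized expression over a shared
    variable-gene panel; ``cnv_categories`` maps chromosome to its
    ordered copy-number category for this subpopulation.
    """

    sample: str
    subcluster: str
    n_cells: int
    centroid: pd.Series
    cnv_categories: dict[str, int]
    deg_set: set[str] = field(default_factory=set)

    @property
    def id(self) -> str:
        return f"{self.sample}/{self.subcluster}"


@dataclass
class TrackingResult:
    """One-to-one matches across timepoints plus per-profile patterns."""

    matches: pd.DataFrame  # columns: t1, t2, similarity
    patterns: pd.DataFrame  # columns: timepoint, profile, pattern

    def pattern_of(self, timepoint: str, profile_id: str) -> str:
        sel = (self.patterns["timepoint"] == timepoint) & (
            self.patterns["profile"] == profile_id
        )
        return str(self.patterns.loc[sel, "pattern"].iloc[0])


def profiles_from_anndata(
    adata,
    cluster_col: str,
    panel_genes: list[str],
    cnv_categories: dict[str, dict[str, int]],
    sample: str,
    deg_sets: dict[str, set[str]] | None = None,
) -> list[SubpopulationProfile]:
    """Build subpopulation fingerprints from a log-normalized AnnData."""
    profiles = []
    for cluster in pd.unique(adata.obs[cluster_col].astype(str)):
        cells = adata[adata.obs[cluster_col].astype(str) == cluster]
        centroid = pd.Series(
            np.asarray(cells[:, panel_genes].X.mean(axis=0)).ravel(),
            index=panel_genes,
        )
        profiles.append(
            SubpopulationProfile(
                sample=sample,
                subcluster=cluster,
                n_cells=cells.n_obs,
                centroid=centroid,
                cnv_categories=dict(cnv_categories.get(cluster, {})),
                deg_set=set() if deg_sets is None else set(
                    deg_sets.get(cluster, set())
                ),
            )
        )
    return profiles


def _similarity(
    a: SubpopulationProfile, b: SubpopulationProfile,
    w_expr: float, w_cnv: float,
) -> float:
    x = a.centroid.to_numpy(dtype=float)
    y = b.centroid.reindex(a.centroid.index).to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    chroms = sorted(set(a.cnv_categories) & set(b.cnv_categories))
    if chroms:
        concord = float(
            np.mean([a.cnv_categories[c] == b.cnv_categories[c]
                     for c in chroms])
        )
    else:
        concord = 0.0
    return w_expr * r + w_cnv * concord


def match_subpopulations(
    profiles_t1: list[SubpopulationProfile],
    profiles_t2: list[SubpopulationProfile],
    w_expr: float = 0.5,
    w_cnv: float = 0.5,
    match_thresh: float = 0.6,
) -> TrackingResult:
    """Match subpopulations across adjacent timepoints.

    Pairwise similarity is ``w_expr`` times the Pearson correlation of
    expression centroids plus ``w_cnv`` times the fraction of
    chromosomes with concordant copy-number categories.  Pairs are
    accepted greedily in decreasing similarity, one-to-one, stopping
    below ``match_thresh``.  Matched profiles are "stable"; profiles
    left unmatched at the later timepoint are "gained", at the earlier
    timepoint "lost".
    """
    sims = []
    for i, a in enumerate(profiles_t1):
        for j, b in enumerate(profiles_t2):
            sims.append((_similarity(a, b, w_expr, w_cnv), i, j))
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    matches = []
    for sim, i, j in sims:
        if sim < match_thresh:
            break
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matches.append((profiles_t1[i].id, profiles_t2[j].id, sim))
    pattern_rows = []
    for i, p in enumerate(profiles_t1):
        pattern_rows.append(
            ("t1", p.id, "stable" if i in used1 else "lost")
        )
    for j, p in enumerate(profiles_t2):
        pattern_rows.append(
            ("t2", p.id, "stable" if j in used2 else "gained")
        )
    return TrackingResult(
        matches=pd.DataFrame(matches, columns=["t1", "t2", "similarity"]),
        patterns=pd.DataFrame(
            pattern_rows, columns=["timepoint", "profile", "pattern"]
        ),
    )


# ---------------------------------------------------------------------------
# QC stratification
# ---------------------------------------------------------------------------


def qc_stratified_check(
    adata,
    gene_set: set[str],
    ngene_thresh: int = 1_000,
    cell_type_col: str = "cell_type",
    ngene_col: str = "n_genes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-program expression per cell type, stratified by gene count.

    Cells are split into strata by expressed-gene count (>= and <
    ``ngene_thresh``).  For every cell type and stratum the mean
    log-normalized expression of ``gene_set`` is reported; per cell
    type, a Mann-Whitney statistic compares the per-cell program score
    between the two strata (NaN with a warning when a stratum is
    empty).  Genes absent from the matrix contribute nothing; a fully
    absent gene set yields all-zero means.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    genes = [g for g in gene_set if g in adata.var_names]
    if genes:
        score = np.asarray(adata[:, genes].X.mean(axis=1)).ravel()
    else:
        score = np.zeros(adata.n_obs)
    obs = pd.DataFrame(
        {
            "cell_type": adata.obs[cell_type_col].astype(str).to_numpy(),
            "stratum": np.where(
                adata.obs[ngene_col].to_numpy() >= ngene_thresh,
                f"nGene>={ngene_thresh}", f"nGene<{ngene_thresh}",
            ),
            "score": score,
        }
    )
    means = (
        obs.groupby(["cell_type", "stratum"], sort=True)["score"]
        .agg(["mean", "size"])
        .rename(columns={"size": "n_cells", "mean": "mean_expression"})
        .reset_index()
    )
    stat_rows = []
    for ct, sub in obs.groupby("cell_type", sort=True):
        hi = sub.loc[sub["stratum"] == f"nGene>={ngene_thresh}", "score"]
        lo = sub.loc[sub["stratum"] == f"nGene<{ngene_thresh}", "score"]
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(
                f"empty stratum for cell type {ct!r}", stacklevel=2
            )
            stat_rows.append((ct, np.nan, np.nan))
            continue
        u, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        stat_rows.append((ct, float(u), float(p)))
    stats_df = pd.DataFrame(
        stat_rows, columns=["cell_type", "mannwhitney_u", "pval"]
    )
    return means, stats_df
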