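"""Ordered copy-number categorization and CNV-panel subclustering.

Copy-number changes from heterogeneous platforms are described with
five ordered categories, deletion < loss < neutral < gain <
amplification, by cutting the log2 copy-ratio axis at platform-specific
cutoffs: (-1, -0.25, 0.2, 0.7) for bulk callers and (-1, -0.4, 0.3,
0.7) for single-cell RNA inference after transforming its relative
intensities to the log2 scale.  A boundary value belongs to the higher
category.  Chromosome-level deletion flags use the linear relative copy
value (neutral = 1.0) with a strict threshold (default < 0.76).  Cells
are subclustered on a CNV gene panel by DBSCAN after PCA, with epsilon
and minimum points chosen by silhouette grid search.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "CnvCategory",
    "CnvSegment",
    "BULK_CUTOFFS",
    "SCRNA_CUTOFFS",
    "categorize",
    "infercnv_to_log2",
    "chrom_deletion_flag",
    "SubclusterResult",
    "dbscan_subcluster",
]


class CnvCategory(enum.IntEnum):
    """Five ordered copy-number levels."""

    DELETION = 0
    LOSS = 1
    NEUTRAL = 2
    GAIN = 3
    AMPLIFICATION = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


BULK_CUTOFFS = (-1.0, -0.25, 0.2, 0.7)
SCRNA_CUTOFFS = (-1.0, -0.4, 0.3, 0.7)
_CUTOFFS = {"bulk": BULK_CUTOFFS, "scrna": SCRNA_CUTOFFS}


@dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment with its log2 ratio and source platform."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    platform: str = "bulk"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if not np.isfinite(self.log2_ratio):
            raise ValueError("log2 ratio must be finite")

    @property
    def category(self) -> CnvCategory:
        return categorize(self.log2_ratio, self.platform)


def categorize(log2_ratio, platform: str = "bulk"):
    """Map log2 copy-ratio value(s) to the ordered five-level scheme.

    With cutoffs (c1, c2, c3, c4): deletion if x < c1, loss if
    c1 <= x < c2, neutral if c2 <= x < c3, gain if c3 <= x < c4,
    amplification if x >= c4.  Accepts scalars or arrays.
    """
    if platform not in _CUTOFFS:
        raise ValueError(f"unknown platform {platform!r}; use 'bulk' or 'scrna'")
    x = np.asarray(log2_ratio, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log2 ratio must be finite")
    idx = np.digitize(x, _CUTOFFS[platform], right=False)
    if np.isscalar(log2_ratio) or x.ndim == 0:
        return CnvCategory(int(idx))
    out = np.empty(x.shape, dtype=object)
    out.ravel()[:] = [CnvCategory(int(i)) for i in idx.ravel()]
    return out


def infercnv_to_log2(
    intensity, clip: float = 3.0, floor: float = 1e-3
):
    """log2-transform relative copy intensities (neutral = 1 maps to 0).

    Non-positive intensities are clipped to ``floor`` with a warning;
    output is clipped to [-clip, clip].
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(x <= 0):
        warnings.warn(
            "non-positive intensity clipped before log2", stacklevel=2
        )
        x = np.where(x <= 0, floor, x)
    out = np.clip(np.log2(x), -clip, clip)
    if np.isscalar(intensity):
        return float(out)
    return out


def chrom_deletion_flag(
    profile: pd.DataFrame,
    chrom: str,
    gene_chroms: pd.Series,
    threshold: float = 0.76,
) -> tuple[pd.Series, bool]:
    """Flag cells whose mean relative copy value on ``chrom`` is below
    ``threshold`` (strict), on the linear scale where neutral = 1.

    ``profile`` is cells x genes of relative copy values; ``gene_chroms``
    maps gene to chromosome.  Returns the per-cell flags and the
    sample-level flag (any cell flagged).
    """
    genes = gene_chroms.index[gene_chroms == chrom].intersection(
        profile.columns
    )
    if len(genes) == 0:
        raise ValueError(f"chromosome {chrom!r} absent from profile")
    values = profile[genes]
    if (values.to_numpy() <= 0).any():
        raise ValueError("relative copy values must be > 0")
    per_cell = values.mean(axis=1) < threshold
    return per_cell, bool(per_cell.any())


@dataclass
class SubclusterResult:
    """Outcome of the silhouette-selected density subclustering.

    ``silhouette`` is the mean silhouette over non-noise points for the
    chosen parameters; ``score`` is the selection criterion (silhouette
    times the fraction of points assigned to a cluster).
    """

    labels: pd.Series  # -1 marks noise
    eps: float
    min_samples: int
    silhouette: float
    score: float
    n_clusters: int
    grid: pd.DataFrame  # one row per evaluated grid point


def _default_eps_grid(x: np.ndarray, n: int = 20) -> np.ndarray:
    d = pdist(x)
    d = d[d > 0]
    if len(d) == 0:
        return np.array([1.0])
    lo, hi = np.percentile(d, [5, 95])
    lo = max(lo, 1e-6)
    return np.geomspace(lo, max(hi, lo * 1.0001), n)


def dbscan_subcluster(
    cnv_matrix: pd.DataFrame,
    eps_grid: np.ndarray | None = None,
    minpts_grid: tuple[int, ...] = (5, 10, 15, 20),
    n_components: int = 10,
    seed: int = 0,
) -> SubclusterResult:
    """Subcluster cells on a CNV gene panel by density clustering.

    The matrix (cells x panel genes) is reduced to its top
    ``n_components`` principal components, DBSCAN is run over the
    (eps, min_samples) grid, and the grid point maximizing the mean
    silhouette over non-noise points, weighted by the fraction of
    points assigned to a cluster — requiring at least two clusters — is
    selected, ties broken toward larger eps then larger min_samples.
    (The weighting keeps the search from collapsing onto tiny dense
    cores that label most cells noise, which the raw non-noise
    silhouette rewards.)
    The default eps grid spans the 5th–95th percentile of pairwise
    distances in 20 log-spaced steps.  If no grid point yields two
    clusters, all cells are returned as a single cluster with a warning.
    """
    if cnv_matrix.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    if cnv_matrix.shape[1] == 0:
        raise ValueError("empty gene panel")
    x = cnv_matrix.to_numpy(dtype=float)
    k = min(n_components, min(x.shape) - 1)
    if k >= 1 and x.shape[1] > k:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x = PCA(n_components=k, svd_solver="full",
                    random_state=seed).fit_transform(x)
    if eps_grid is None:
        eps_grid = _default_eps_grid(x)

    rows = []
    best = None  # (score, eps, minpts, silhouette, labels)
    for eps in eps_grid:
        for minpts in minpts_grid:
            labels = DBSCAN(eps=float(eps), min_samples=int(minpts)).fit_predict(x)
            keep = labels >= 0
            n_clusters = len(set(labels[keep]))
            if n_clusters >= 2 and keep.sum() > n_clusters:
                sil = float(silhouette_score(x[keep], labels[keep]))
                score = sil * float(keep.mean())
            else:
                sil = score = np.nan
            rows.append(
                {"eps": float(eps), "min_samples": int(minpts),
                 "n_clusters": n_clusters, "silhouette": sil, "score": score}
            )
            if not np.isnan(score):
                cand = (score, float(eps), int(minpts))
                if best is None or cand > (best[0], best[1], best[2]):
                    best = (score, float(eps), int(minpts), sil, labels)
    grid = pd.DataFrame(rows)
    if best is None:
        warnings.warn(
            "no (eps, min_samples) grid point produced >= 2 clusters; "
            "returning a single cluster", stacklevel=2,
        )
        labels = pd.Series(0, index=cnv_matrix.index, name="subcluster")
        return SubclusterResult(labels, float(eps_grid[-1]),
                                int(minpts_grid[0]), np.nan, np.nan, 1, grid)
    score, eps, minpts, sil, labels = best
    return SubclusterResult(
        labels=pd.Series(labels, index=cnv_matrix.index, name="subcluster"),
        eps=eps,
        min_samples=minpts,
        silhouette=sil,
        score=score,
        n_clusters=len(set(labels[labels >= 0])),
        grid=grid,
    )
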