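"""Ancestry inference from allele read counts.

Genotypes are called from per-marker reference/alternate read counts by
fixed depth thresholds (hom-ref when ref >= 8 and alt < 4; het when
ref >= 4 and alt >= 4; hom-alt when ref < 4 and alt >= 8; missing
otherwise).  Markers missing in more than 5% of query samples are
dropped.  A reference panel with known population labels is reduced to
its top principal components (default 20) on centered/scaled dosages,
a random-forest classifier is trained on the components with an 80/20
stratified split, and query samples are projected into the reference
space — using the reference centering and scaling, never refit — and
classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "GENOTYPE_CODES",
    "call_genotype",
    "call_genotype_matrix",
    "filter_markers",
    "ProjectionModel",
    "fit_projection",
    "project_and_classify",
]

# dosage codes; -1 marks a missing call
GENOTYPE_CODES = {"hom-ref": 0, "het": 1, "hom-alt": 2, "missing": -1}


def call_genotype(ref_count: int, alt_count: int) -> str:
    """Threshold genotype call from allele read counts.

    hom-ref if ref >= 8 and alt < 4; het if ref >= 4 and alt >= 4;
    hom-alt if ref < 4 and alt >= 8; missing otherwise.  The three
    positive rules are mutually exclusive, so exactly one outcome fires
    for every non-negative count pair.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if ref_count >= 8 and alt_count < 4:
        return "hom-ref"
    if ref_count >= 4 and alt_count >= 4:
        return "het"
    if ref_count < 4 and alt_count >= 8:
        return "hom-alt"
    return "missing"


def call_genotype_matrix(ref: pd.DataFrame, alt: pd.DataFrame) -> pd.DataFrame:
    """Vectorized genotype calling; returns dosage codes (missing = -1)."""
    if (ref.to_numpy() < 0).any() or (alt.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    r = ref.to_numpy()
    a = alt.to_numpy()
    out = np.full(r.shape, GENOTYPE_CODES["missing"], dtype=np.int8)
    out[(r >= 8) & (a < 4)] = GENOTYPE_CODES["hom-ref"]
    out[(r >= 4) & (a >= 4)] = GENOTYPE_CODES["het"]
    out[(r < 4) & (a >= 8)] = GENOTYPE_CODES["hom-alt"]
    return pd.DataFrame(out, index=ref.index, columns=ref.columns)


def filter_markers(
    genotype_matrix: pd.DataFrame, max_missing_frac: float = 0.05
) -> pd.Index:
    """Markers whose missing fraction is at most ``max_missing_frac``."""
    if genotype_matrix.size == 0:
        raise ValueError("empty genotype matrix")
    missing_frac = (genotype_matrix == GENOTYPE_CODES["missing"]).mean(axis=0)
    return genotype_matrix.columns[missing_frac <= max_missing_frac]


@dataclass
class ProjectionModel:
    """Reference PCA space plus a trained ancestry classifier.

    Stores the per-marker centering means and scale factors of the
    reference dosages, the top-K loading vectors, the reference
    coordinates with their population labels, the fitted classifier,
    and the held-out accuracy from the stratified train/test split.
    """

    markers: pd.Index
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # K x n_markers, rows orthonormal
    reference_coords: pd.DataFrame
    labels: pd.Series
    classifier: RandomForestClassifier
    holdout_accuracy: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def save(self, path: str) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "ProjectionModel":
        import joblib

        return joblib.load(path)


def _standardize(
    dosage: np.ndarray, center: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """Impute missing (-1) with the reference marker mean, center, scale."""
    x = dosage.astype(float)
    miss = x < 0
    if miss.any():
        x[miss] = np.broadcast_to(center, x.shape)[miss]
    return (x - center) / scale


def fit_projection(
    reference_matrix: pd.DataFrame,
    labels: pd.Series,
    n_components: int = 20,
    split_frac: float = 0.2,
    seed: int = 0,
    n_trees: int = 500,
) -> ProjectionModel:
    """Fit the reference PCA space and ancestry classifier.

    ``reference_matrix`` holds dosage codes (0/1/2, -1 missing) for the
    reference panel; missing entries are imputed with the per-marker
    mean of the observed calls, markers are centered and scaled to unit
    variance (sd floored at 1e-8), and the top ``n_components``
    principal components are retained.  A random forest is trained on
    the components with a stratified ``1 - split_frac`` / ``split_frac``
    train/test split and its held-out accuracy stored; the model's
    classifier itself is refit on all reference samples.
    """
    labels = labels.loc[reference_matrix.index]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two populations")
    if (counts < 2).any():
        raise ValueError(
            f"population(s) with <2 samples: {list(counts[counts < 2].index)}"
        )
    if reference_matrix.shape[1] < n_components:
        raise ValueError("fewer markers than requested components")

    dosage = reference_matrix.to_numpy()
    masked = np.where(dosage < 0, np.nan, dosage).astype(float)
    center = np.nanmean(masked, axis=0)
    center = np.where(np.isnan(center), 0.0, center)
    scale = np.nanstd(masked, axis=0)
    scale = np.where(np.isnan(scale) | (scale < 1e-8), 1e-8, scale)
    x = _standardize(dosage, center, scale)

    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(x)
    # fold the PCA's own (near-zero) centering into the marker means so
    # projection is a single affine map
    center = center + pca.mean_ * scale
    loadings = pca.components_

    x_train, x_test, y_train, y_test = train_test_split(
        coords, labels.to_numpy(), test_size=split_frac,
        stratify=labels.to_numpy(), random_state=seed,
    )
    holdout = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(x_train, y_train)
    accuracy = float(holdout.score(x_test, y_test))
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(coords, labels.to_numpy())

    return ProjectionModel(
        markers=reference_matrix.columns,
        center=center,
        scale=scale,
        loadings=loadings,
        reference_coords=pd.DataFrame(
            coords, index=reference_matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        labels=labels,
        classifier=clf,
        holdout_accuracy=accuracy,
    )


def project_and_classify(
    model: ProjectionModel, query_matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Project query dosages into the reference space and classify.

    Query markers are intersected with the model's markers (markers the
    query lacks are treated as missing and imputed with the reference
    mean); the intersection must contain at least as many markers as
    components.  The query is centered and scaled with the reference
    statistics — the PCA is never refit.  Returns coordinates,
    predicted population labels, and class probabilities.
    """
    shared = model.markers.intersection(query_matrix.columns)
    if len(shared) < model.n_components:
        raise ValueError(
            f"query shares {len(shared)} markers with the model; "
            f"need >= {model.n_components}"
        )
    aligned = query_matrix.reindex(columns=model.markers, fill_value=-1)
    dosage = aligned.to_numpy()
    if ((dosage < 0).all(axis=1)).any():
        bad = aligned.index[(dosage < 0).all(axis=1)]
        raise ValueError(f"all-missing query sample(s): {list(bad)}")
    x = _standardize(dosage, model.center, model.scale)
    coords = x @ model.loadings.T
    coords = pd.DataFrame(
        coords, index=query_matrix.index,
        columns=[f"PC{i + 1}" for i in range(model.n_components)],
    )
    pred = pd.Series(
        model.classifier.predict(coords.to_numpy()),
        index=query_matrix.index, name="predicted_population",
    )
    proba = pd.DataFrame(
        model.classifier.predict_proba(coords.to_numpy()),
        index=query_matrix.index, columns=model.classifier.classes_,
    )
    return coords, pred, proba
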