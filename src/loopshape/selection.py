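"""Representative-model selection from descriptor matrices.

The pipeline mirrors the common practice for picking a small, diverse set of
starting structures from a large conformer ensemble: standardize the
mixed-unit descriptor columns, reduce them with PCA to the leading
components, partition the models with K-means, and return one actual model
per cluster — the cluster medoid, i.e. the member minimizing the summed
Euclidean distance to all members of its cluster in the reduced space. The
lowest-DOPE model is reported alongside as the conventional single-model
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .descriptors import SCORE_NAMES
from .errors import InputError
from .structure_io import ScoreRecord


@dataclass
class SelectionConfig:
    """Parameters of the selection pipeline.

    variance_retained: fraction of total variance the kept principal
        components must explain (components are added in eigenvalue order
        until the cumulative fraction reaches this threshold).
    k: number of K-means clusters, i.e. of representatives returned.
    use_scores: include the dope/soap columns (when present) alongside the
        geometric descriptors in the standardized input to PCA.
    """

    variance_retained: float = 0.95
    k: int = 3
    seed: int = 0
    n_init: int = 10
    use_scores: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_retained <= 1.0):
            raise InputError("variance_retained must lie in (0, 1]")
        if self.k < 1:
            raise InputError("k must be >= 1")
        if self.n_init < 1:
            raise InputError("n_init must be >= 1")


@dataclass
class SelectionResult:
    """PCA summary, cluster labels and the chosen representative models."""

    component_loadings: np.ndarray  # P x m
    explained_variance: np.ndarray  # m fractions
    labels: np.ndarray  # N cluster indices
    representatives: list[tuple[int, str]]  # (cluster, model_id)
    lowest_dope_id: Optional[str] = None
    feature_names: list[str] = field(default_factory=list)
    model_ids: list[str] = field(default_factory=list)
    reduced: Optional[np.ndarray] = None
    config: Optional[SelectionConfig] = None

    def to_dict(self) -> dict:
        out = {
            "explained_variance": [float(v) for v in self.explained_variance],
            "component_loadings": self.component_loadings.tolist(),
            "feature_names": list(self.feature_names),
            "labels": {m: int(l) for m, l in zip(self.model_ids, self.labels)},
            "representatives": [
                {"cluster": int(c), "model_id": m} for c, m in self.representatives
            ],
            "lowest_dope_id": self.lowest_dope_id,
        }
        if self.config is not None:
            out["config"] = {
                "variance_retained": self.config.variance_retained,
                "k": self.config.k,
                "seed": self.config.seed,
                "n_init": self.config.n_init,
                "use_scores": self.config.use_scores,
            }
        return out


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample (ddof=1) sd 1.

    Zero-variance columns are mapped to all-zeros with a warning rather than
    dividing by zero. Missing values are an error naming the columns.
    """
    if len(matrix) < 2:
        raise InputError("standardization needs at least 2 rows")
    bad = [c for c in matrix.columns if matrix[c].isna().any()]
    if bad:
        raise InputError(f"missing values in column(s) {bad}")
    out = matrix.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=1)
        mean = out[col].mean()
        if sd == 0.0:
            warnings.warn(f"column {col!r} has zero variance; set to zeros", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (out[col] - mean) / sd
    return out


def pca_reduce(
    matrix: pd.DataFrame, variance_retained: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on a standardized matrix, keeping the fewest components whose
    cumulative explained variance reaches ``variance_retained``.

    Returns (reduced N×m scores, P×m loadings, m explained-variance
    fractions). Components are eigenvectors of the sample covariance matrix
    in descending eigenvalue order; each component is sign-fixed so its
    largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise InputError("PCA needs at least 2 rows")
    if np.isnan(X).any():
        raise InputError("PCA input contains missing values")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    m = int(np.searchsorted(cumulative, variance_retained - 1e-12) + 1)
    m = min(m, len(ratios))

    loadings = pca.components_[:m].T.copy()  # P x m
    scores = scores[:, :m].copy()
    for j in range(m):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return scores, loadings, ratios[:m].copy()


def kmeans_cluster(
    reduced: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means (k-means++ init, best inertia over n_init restarts).

    Deterministic for a fixed seed. Returns (labels, centroids).
    """
    reduced = np.asarray(reduced, dtype=float)
    if reduced.ndim == 1:
        reduced = reduced[:, None]
    if k > reduced.shape[0]:
        raise InputError(f"k={k} exceeds the number of points ({reduced.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(reduced)
    return labels, km.cluster_centers_


def select_representatives(
    reduced: np.ndarray, labels: np.ndarray, model_ids: Sequence[str]
) -> list[tuple[int, str]]:
    """Per cluster, the medoid: the member minimizing the sum of Euclidean
    distances to all members of its cluster; ties break to the lowest model
    index. Returned sorted by cluster index.
    """
    reduced = np.asarray(reduced, dtype=float)
    if reduced.ndim == 1:
        reduced = reduced[:, None]
    labels = np.asarray(labels)
    model_ids = list(model_ids)
    reps: list[tuple[int, str]] = []
    for cluster in sorted(set(int(l) for l in labels)):
        idx = np.flatnonzero(labels == cluster)
        pts = reduced[idx]
        dist_sums = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2).sum(axis=1)
        best = idx[int(np.argmin(dist_sums))]  # argmin takes first minimum: lowest index
        reps.append((cluster, model_ids[best]))
    return reps


def lowest_dope(scores: Sequence[ScoreRecord]) -> str:
    """Model id with the minimum DOPE score; ties go to the first in order."""
    if not scores:
        raise InputError("empty score list")
    best = min(scores, key=lambda r: r.dope)  # min() keeps the first minimum
    return str(best.model_id)


def run_selection(
    matrix: pd.DataFrame,
    scores: Optional[Sequence[ScoreRecord]] = None,
    config: Optional[SelectionConfig] = None,
) -> SelectionResult:
    """Full pipeline: standardize → PCA → K-means → medoid per cluster.

    ``matrix`` is a descriptor matrix (model ids as index). Columns that are
    entirely NaN (undefined descriptors, e.g. no protein context) are
    dropped before standardization. When score records are given, the
    lowest-DOPE baseline id is reported; their dope/soap columns join the
    features unless the config says geometry only.
    """
    config = config or SelectionConfig()
    if config.k > len(matrix):
        raise InputError(f"k={config.k} exceeds ensemble size {len(matrix)}")

    features = matrix.copy()
    features = features.drop(
        columns=[c for c in features.columns if features[c].isna().all()]
    )
    if not config.use_scores:
        features = features.drop(columns=[c for c in SCORE_NAMES if c in features.columns])
    if scores is not None and config.use_scores:
        by_id = {str(r.model_id): r for r in scores}
        missing = [m for m in features.index if str(m) not in by_id]
        if missing:
            raise InputError(f"no score record for model id(s) {missing}")
        if "dope" not in features.columns:
            features["dope"] = [by_id[str(m)].dope for m in features.index]
        if "soap" not in features.columns:
            features["soap"] = [by_id[str(m)].soap for m in features.index]

    standardized = standardize(features)
    reduced, loadings, explained = pca_reduce(standardized, config.variance_retained)
    labels, _ = kmeans_cluster(reduced, config.k, seed=config.seed, n_init=config.n_init)
    model_ids = [str(m) for m in matrix.index]
    representatives = select_representatives(reduced, labels, model_ids)

    lowest = None
    if scores is not None:
        lowest = lowest_dope(list(scores))
    elif "dope" in matrix.columns:
        lowest = str(matrix["dope"].idxmin())

    return SelectionResult(
        component_loadings=loadings,
        explained_variance=explained,
        labels=labels,
        representatives=representatives,
        lowest_dope_id=lowest,
        feature_names=list(standardized.columns),
        model_ids=model_ids,
        reduced=reduced,
        config=config,
    )


def silhouette_sweep(
    reduced: np.ndarray, k_range: Sequence[int] = range(2, 11), seed: int = 0, n_init: int = 10
) -> dict[int, float]:
    """Mean silhouette score for each k in ``k_range`` (reported, not applied)."""
    from sklearn.metrics import silhouette_score

    reduced = np.asarray(reduced, dtype=float)
    out = {}
    for k in k_range:
        if k >= reduced.shape[0]:
            continue
        labels, _ = kmeans_cluster(reduced, k, seed=seed, n_init=n_init)
        out[int(k)] = float(silhouette_score(reduced, labels))
    return out
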