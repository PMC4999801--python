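"""Unsupervised 3-class pixel segmentation in the 10-dim feature space.

k-means (k = 3, k-means++ seeding, best of several restarts) clusters
the standardized feature vectors; clusters are then identified as DAB
nuclei, hematoxylin nuclei or background from their raw channel
statistics: the DAB cluster has the lowest mean blue intensity (brown
pigment absorbs blue), and of the remaining two the hematoxylin cluster
has the highest mean hue (blue sits near 240 deg, the bright background
near 0).  This identification rule is an inference from the stain
chemistry, not a supervised step.

Standardization matters: without it the hue channel (0-360) and the
raw intensities (0-255) would dominate the window moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError
from .features import FeatureMatrix, assemble_features
from .io_images import CLASS_BACKGROUND, CLASS_DAB, CLASS_HEMATOXYLIN, to_channel_planes
from .preprocess import PreprocessParams, smooth_enhance

logger = logging.getLogger(__name__)

K = 3  # DAB nuclei, hematoxylin nuclei, background


@dataclass(frozen=True)
class ClusterModel:
    """Fitted pixel-cluster model in standardized feature units."""

    centroids: np.ndarray          # (3, 10), standardized space
    feature_means: np.ndarray      # (10,)
    feature_sds: np.ndarray        # (10,), constant features get sd 1
    seed: int
    tol: float
    max_iter: int
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def predict(self, std_matrix: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for standardized rows."""
        d2 = (
            (std_matrix * std_matrix).sum(axis=1)[:, None]
            - 2.0 * std_matrix @ self.centroids.T
            + (self.centroids * self.centroids).sum(axis=1)[None, :]
        )
        return np.argmin(d2, axis=1)


def standardize_features(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each column; zero-variance columns are centered, divisor 1."""
    values = np.asarray(values, dtype=np.float64)
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    return (values - means) / sds, means, sds


def apply_standardization(values, means, sds) -> np.ndarray:
    return (np.asarray(values, dtype=np.float64) - means) / sds


def fit_clusters(
    std_matrix: np.ndarray,
    seed: int = 42,
    tol: float = 1e-4,
    max_iter: int = 300,
    restarts: int = 5,
    subsample_n: int = 50_000,
) -> ClusterModel:
    """Lloyd iterations with k-means++ seeding on (optionally subsampled) rows.

    If ``subsample_n > 0`` and the matrix is larger, centroids are fitted
    on a uniform random subsample (same seed) for desk-scale runtime;
    assignment of all pixels is always exact nearest-centroid.
    Convergence: max centroid displacement < tol, or max_iter sweeps.
    """
    std_matrix = np.asarray(std_matrix, dtype=np.float64)
    fit_rows = std_matrix
    if subsample_n and std_matrix.shape[0] > subsample_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(std_matrix.shape[0], size=subsample_n, replace=False)
        fit_rows = std_matrix[idx]
    distinct = np.unique(fit_rows, axis=0).shape[0]
    if distinct < K:
        raise DegenerateInputError(
            f"need at least {K} distinct feature rows to form {K} clusters, found {distinct}"
        )
    km = KMeans(
        n_clusters=K, init="k-means++", n_init=restarts,
        tol=tol, max_iter=max_iter, random_state=seed,
    ).fit(fit_rows)
    # deterministic centroid order: sort rows lexicographically
    order = np.lexsort(km.cluster_centers_.T[::-1])
    return ClusterModel(
        centroids=km.cluster_centers_[order].copy(),
        feature_means=np.zeros(std_matrix.shape[1]),
        feature_sds=np.ones(std_matrix.shape[1]),
        seed=seed, tol=tol, max_iter=max_iter, inertia=float(km.inertia_),
    )


def map_clusters_to_classes(
    model: ClusterModel, fm: FeatureMatrix, assignments: np.ndarray
) -> dict[int, int]:
    """Identify each cluster as DAB / HEMATOXYLIN / BACKGROUND.

    Rule: DAB = cluster with minimum mean raw I_b; of the remaining two,
    HEMATOXYLIN = maximum mean raw I_h; BACKGROUND = the rest.  Raises
    DegenerateInputError if any cluster is empty (callers re-fit with
    seed+1).
    """
    i_b = fm.values[:, fm.columns.index("I_b")]
    i_h = fm.values[:, fm.columns.index("I_h")]
    stats = {}
    for c in range(model.k):
        members = assignments == c
        if not members.any():
            raise DegenerateInputError(f"cluster {c} is empty")
        stats[c] = (i_b[members].mean(), i_h[members].mean())
    dab = min(stats, key=lambda c: stats[c][0])
    rest = [c for c in stats if c != dab]
    hema = max(rest, key=lambda c: stats[c][1])
    (bg,) = [c for c in rest if c != hema]
    return {dab: CLASS_DAB, hema: CLASS_HEMATOXYLIN, bg: CLASS_BACKGROUND}


def segment_features(
    fm: FeatureMatrix,
    seed: int = 42,
    tol: float = 1e-4,
    max_iter: int = 300,
    restarts: int = 5,
    subsample_n: int = 50_000,
    max_retries: int = 3,
) -> tuple[np.ndarray, ClusterModel]:
    """Cluster a feature matrix and return the (H, W) class map + model.

    An empty cluster (possible on pathological inputs) triggers a re-fit
    with seed+1, up to ``max_retries`` times.
    """
    std, means, sds = standardize_features(fm.values)
    last_exc: Exception | None = None
    for attempt in range(max_retries + 1):
        try:
            model = fit_clusters(
                std, seed=seed + attempt, tol=tol, max_iter=max_iter,
                restarts=restarts, subsample_n=subsample_n,
            )
            assignments = model.predict(std)
            mapping = map_clusters_to_classes(model, fm, assignments)
        except DegenerateInputError as exc:
            if "distinct" in str(exc):
                raise
            logger.warning("empty cluster with seed %d, retrying with seed %d",
                           seed + attempt, seed + attempt + 1)
            last_exc = exc
            continue
        model = ClusterModel(
            centroids=model.centroids, feature_means=means, feature_sds=sds,
            seed=model.seed, tol=model.tol, max_iter=model.max_iter,
            inertia=model.inertia,
        )
        lut = np.empty(model.k, dtype=np.uint8)
        for cluster, cls in mapping.items():
            lut[cluster] = cls
        return lut[assignments].reshape(fm.height, fm.width), model
    raise last_exc  # type: ignore[misc]


def classify_pixels(
    img: np.ndarray,
    preprocess_params: PreprocessParams | None = None,
    seed: int = 42,
    tol: float = 1e-4,
    max_iter: int = 300,
    restarts: int = 5,
    subsample_n: int = 50_000,
    excess_kurtosis: bool = False,
) -> tuple[np.ndarray, ClusterModel]:
    """Full pixel classification: preprocess -> planes -> features ->
    standardize -> k-means -> class identification.

    Returns the (H, W) class map (values CLASS_*) and the fitted model.
    Deterministic given (image, parameters, seed).
    """
    smoothed = smooth_enhance(img, preprocess_params)
    planes = to_channel_planes(smoothed)
    fm = assemble_features(planes, excess_kurtosis=excess_kurtosis)
    return segment_features(
        fm, seed=seed, tol=tol, max_iter=max_iter,
        restarts=restarts, subsample_n=subsample_n,
    )
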