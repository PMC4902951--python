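"""Initialization machinery: imputation, k-means seeding, BIC for k, warm starts.

The coordinate-ascent learner needs a starting gene-to-module assignment.
The standard chain is: complete the merged genes x samples matrix by
iterative PCA (genes unmeasured in a study are missing cells), run k-means
on the completed matrix to get initial modules, optionally run the
single-matrix module learner on the completed data (the imputation-based
baseline) and hand its final assignment to the joint learner as a warm
start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import core
from .datamodel import StudyCollection

__all__ = [
    "ImputedMatrix",
    "iterative_pca_impute",
    "merged_matrix",
    "kmeans_assign",
    "select_k_bic",
    "kmeans_bic",
    "default_init",
    "warm_start",
]


@dataclass
class ImputedMatrix:
    """A completed p_T x n_T matrix over the gene universe and all samples."""

    values: np.ndarray
    observed_mask: np.ndarray
    n_components: int
    iterations_run: int
    converged: bool
    gene_ids: list[str]
    sample_ids: list[str]


def merged_matrix(collection: StudyCollection) -> tuple[np.ndarray, np.ndarray]:
    """Stack all datasets over the universe; NaN where a gene was unmeasured."""
    p, n = collection.p_total, collection.n_total
    values = np.full((p, n), np.nan)
    mask = np.zeros((p, n), dtype=bool)
    col = 0
    for q, ds in enumerate(collection.datasets):
        rows = collection.dataset_rows[q]
        values[rows, col : col + ds.n_samples] = ds.values
        mask[rows, col : col + ds.n_samples] = True
        col += ds.n_samples
    return values, mask


def iterative_pca_impute(
    collection: StudyCollection,
    n_components: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ImputedMatrix:
    """Complete the merged matrix by iterative PCA.

    Missing cells start at 0 (the gene mean after standardization) and are
    repeatedly replaced by the rank-r SVD reconstruction until the relative
    change of the imputed entries drops below ``tol``.  Observed cells are
    never touched.
    """
    values, mask = merged_matrix(collection)
    p, n = values.shape
    if n_components >= min(p, n):
        raise ValueError(
            f"n_components={n_components} must be < min(p, n) = {min(p, n)}"
        )
    if not mask.any(axis=1).all():  # pragma: no cover - excluded by construction
        raise ValueError("some gene observed in no dataset")
    sample_ids = [s for ds in collection.datasets for s in ds.sample_ids]
    missing = ~mask
    if not missing.any():
        return ImputedMatrix(
            values, mask, n_components, 0, True, list(collection.universe), sample_ids
        )
    filled = values.copy()
    filled[missing] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
        new_vals = recon[missing]
        delta = np.linalg.norm(new_vals - filled[missing])
        scale = np.linalg.norm(filled[missing]) + 1e-12
        filled[missing] = new_vals
        if delta / scale < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"iterative PCA imputation stopped at max_iter={max_iter} without "
            "meeting tol",
            RuntimeWarning,
            stacklevel=2,
        )
    return ImputedMatrix(
        filled, mask, n_components, it, converged, list(collection.universe), sample_ids
    )


def kmeans_assign(
    matrix: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[core.ModuleAssignment, np.ndarray]:
    """Cluster genes (rows) into k modules by k-means over samples.

    Among ``n_restarts`` random initializations the clustering with the
    lowest total within-cluster sum of squares is kept.
    """
    matrix = np.asarray(matrix, dtype=float)
    p = matrix.shape[0]
    if k > p:
        raise ValueError(f"k={k} exceeds number of genes {p}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(matrix)
    if gene_ids is None:
        gene_ids = [f"row{i}" for i in range(p)]
    return core.ModuleAssignment(list(gene_ids), labels, k), km.cluster_centers_


def kmeans_bic(matrix: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a spherical-Gaussian reading of a k-means fit.

    Genes are points in sample space (dimension n); each cluster is a
    spherical Gaussian at its centroid, with one pooled MLE variance shared
    by all clusters (per-cluster variances over-reward splitting tight
    clusters and make the score decrease without bound in k).  The penalty
    is ``(k*n + k) * log p`` (centroid coordinates plus mixing weights).
    """
    p, n = matrix.shape
    wss = 0.0
    for c in range(k):
        pts = matrix[labels == c]
        if pts.shape[0] == 0:
            continue
        wss += ((pts - pts.mean(axis=0)) ** 2).sum()
    var = max(wss / (p * n), 1e-12)
    loglik = -0.5 * p * n * (np.log(2 * np.pi * var) + 1.0)
    penalty = (k * n + k) * np.log(p)
    return -2.0 * loglik + penalty


def select_k_bic(
    matrix: np.ndarray,
    k_grid: list[int],
    seed: int | None = None,
    n_restarts: int = 5,
) -> tuple[int, dict[int, float]]:
    """Pick the module count minimizing the k-means BIC (ties -> smallest k)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to select k")
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    if max(k_grid) > matrix.shape[0]:
        raise ValueError("every k must be <= number of genes")
    scores: dict[int, float] = {}
    for k in sorted(set(int(k) for k in k_grid)):
        assignment, _ = kmeans_assign(matrix, k, n_restarts=n_restarts, seed=seed)
        scores[k] = kmeans_bic(matrix, assignment.labels, k)
    best = min(sorted(scores), key=lambda k: scores[k])
    return best, scores


def default_init(
    collection: StudyCollection,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    impute_rank: int = 5,
) -> core.ModuleAssignment:
    """k-means on the imputed merged matrix: the standard initial assignment."""
    imputed = iterative_pca_impute(collection, n_components=impute_rank)
    assignment, _ = kmeans_assign(
        imputed.values,
        k,
        n_restarts=n_restarts,
        seed=seed,
        gene_ids=collection.universe,
    )
    return assignment


def warm_start(
    collection: StudyCollection,
    k: int,
    lam: float,
    seed: int | None = None,
    sigma: float = 1.0,
    n_restarts: int = 10,
    impute_rank: int = 5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> core.ModuleAssignment:
    """Warm-start chain: impute -> k-means -> single-matrix fit -> final Z.

    Runs the module learner on the completed matrix (the imputation-based
    baseline) and returns its final assignment as the joint learner's
    starting point.
    """
    init = default_init(
        collection, k, seed=seed, n_restarts=n_restarts, impute_rank=impute_rank
    )
    model = core.fit(
        collection,
        k,
        lam,
        sigma=sigma,
        init=init,
        tol=tol,
        max_iter=max_iter,
        mode="imputed",
        impute_rank=impute_rank,
    )
    return model.assignment.restrict(collection.universe)
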