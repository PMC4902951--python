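"""Downstream use of a fitted model: latent features, subtypes, associations.

The fitted module network defines a per-sample low-dimensional representation
(one feature per module).  Features for new samples come from the same
latent linear system used during fitting, with the trained assignment,
precision, and noise scale held fixed; they can then be clustered into
patient subtypes or correlated with phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import InspireModel, _solve_latents
from .datamodel import ExpressionDataset

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "cluster_subtypes",
    "associate_features",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """k x n latent module features for a set of samples."""

    values: np.ndarray
    sample_ids: list[str]
    module_ids: list[int]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.module_ids), len(self.sample_ids)):
            raise ValueError("feature matrix shape mismatch")


def extract_features(model: InspireModel, ds: ExpressionDataset) -> FeatureMatrix:
    """Latent features for ``ds`` under the trained model.

    Solves the latent linear system with the model's fixed assignment,
    precision, and sigma.  Genes in ``ds`` unknown to the model are dropped
    with a logged count; there must be at least one known gene.
    """
    known = {g: i for i, g in enumerate(model.assignment.gene_ids)}
    keep = [g for g in ds.gene_ids if g in known]
    if not keep:
        raise ValueError("no overlap between dataset genes and model universe")
    dropped = ds.n_genes - len(keep)
    if dropped:
        logger.warning("dropping %d genes absent from the model", dropped)
        ds = ds.subset_genes(keep)
    labels = model.assignment.labels[[known[g] for g in ds.gene_ids]]
    L = _solve_latents(ds.values, labels, model.k, model.precision.theta, model.sigma)
    return FeatureMatrix(L, list(ds.sample_ids), list(range(model.k)))


def cluster_subtypes(
    features: FeatureMatrix,
    n_subtypes: int = 4,
    restarts: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Cluster samples into subtypes by k-means over the feature space.

    Best of ``restarts`` random initializations by within-cluster sum of
    squares; label IDs are canonicalized by descending cluster size.
    """
    n = len(features.sample_ids)
    if n_subtypes > n:
        raise ValueError(f"n_subtypes={n_subtypes} exceeds sample count {n}")
    km = KMeans(n_clusters=n_subtypes, n_init=restarts, random_state=seed)
    raw = km.fit_predict(features.values.T)
    sizes = np.bincount(raw, minlength=n_subtypes)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(n_subtypes, dtype=int)
    remap[order] = np.arange(n_subtypes)
    return remap[raw]


def associate_features(
    features: FeatureMatrix, phenotype
) -> list[tuple[float, float]]:
    """Pearson correlation (r, two-sided p) of each feature with a phenotype.

    Missing phenotype values (NaN) are dropped pairwise; at least three
    complete pairs are required and the phenotype must not be constant.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (len(features.sample_ids),):
        raise ValueError("phenotype must align with the feature samples")
    keep = np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-missing phenotype values")
    if np.std(y[keep]) == 0:
        raise ValueError("constant phenotype has no correlation")
    out = []
    for row in features.values:
        r, p = stats.pearsonr(row[keep], y[keep])
        out.append((float(r), float(p)))
    return out
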