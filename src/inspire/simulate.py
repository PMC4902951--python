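"""Synthetic ground-truth models and dataset pairs for recovery experiments.

The generator draws a sparse k x k module precision, samples latent module
activities L ~ N(0, Sigma_L), assigns each of p_T genes uniformly at random
to one module, and emits X = Z L + noise.  The columns of X are split into
two studies (n1 and n2 samples) covering partially overlapping gene subsets,
characterized by a triple [OL, D1, D2]: OL genes shared, D1 only in
dataset 1, D2 only in dataset 2.  A fresh held-out test matrix is drawn from
the same truth.

Sparsity of the precision: each strictly-lower-triangular entry is 0 with
probability (1 - d), Uniform(0, 0.5) with probability d/2 and
Uniform(0.5, 1) with probability d/2; the matrix is symmetrized and the
diagonal set to eps = |min eigenvalue| + 0.1 so the result is positive
definite.

All randomness flows from a single seed; identical seeds give bit-identical
instantiations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import ModuleAssignment
from .datamodel import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "sample_precision",
    "sample_model",
    "split_datasets",
    "make_instantiation",
]

EPS_MARGIN = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic instantiation.

    Defaults are the benchmark conditions: k=10 modules, precision density
    d=0.2, p_T=250 genes, two studies of 20 and 30 samples, 100 held-out
    test samples, observation noise sigma_obs=0.5 (clear but non-degenerate
    module structure on latents whose marginal variances are below 1).
    """

    k: int = 10
    d: float = 0.2
    p_total: int = 250
    setting: tuple[int, int, int] = (150, 100, 0)
    n1: int = 20
    n2: int = 30
    sigma_obs: float = 0.5
    n_test: int = 100

    def __post_init__(self) -> None:
        ol, d1, d2 = self.setting
        if ol + d1 + d2 != self.p_total:
            raise ValueError(
                f"setting {self.setting} must sum to p_total={self.p_total}"
            )
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("density d must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """One complete ground-truth instantiation with its generated datasets."""

    G: np.ndarray
    precision_true: np.ndarray
    epsilon: float
    density: float
    Z_true: ModuleAssignment
    sigma_obs: float
    dataset1: ExpressionDataset
    dataset2: ExpressionDataset
    test_Y: np.ndarray  # p_T x n_test, rows ordered as Z_true.gene_ids
    setting: tuple[int, int, int]
    config: SimulationConfig | None = None

    @property
    def covariance_latent(self) -> np.ndarray:
        return np.linalg.inv(self.precision_true)

    def gene_covariance(self) -> np.ndarray:
        """True gene-level covariance Z Sigma_L Z' + sigma_obs^2 I."""
        Z = self.Z_true.indicator
        return Z @ self.covariance_latent @ Z.T + self.sigma_obs**2 * np.eye(
            Z.shape[0]
        )


def sample_precision(
    k: int, d: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw the sparse true module precision.

    Returns ``(G, precision, eps)`` where G is the strictly-lower-triangular
    draw (zero diagonal) and ``precision = G + G' + eps I``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0.0 <= d <= 1.0:
        raise ValueError("density d must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    G = np.zeros((k, k))
    for i in range(1, k):
        for j in range(i):
            u = rng.random()
            if u < d / 2:
                G[i, j] = rng.uniform(0.0, 0.5)
            elif u < d:
                G[i, j] = rng.uniform(0.5, 1.0)
    sym = G + G.T
    w = np.linalg.eigvalsh(sym)
    eps = abs(float(w.min())) + EPS_MARGIN
    precision = sym + eps * np.eye(k)
    return G, precision, eps


def sample_model(
    precision_true: np.ndarray,
    p_total: int,
    n: int,
    sigma_obs: float,
    seed: int | np.random.Generator,
    gene_ids: list[str] | None = None,
) -> tuple[ModuleAssignment, np.ndarray, np.ndarray]:
    """Draw (Z, L, X): random hard assignments, Gaussian latents, noisy genes."""
    k = precision_true.shape[0]
    if p_total < k:
        raise ValueError("p_total must be >= k so modules can be populated")
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be non-negative")
    rng = np.random.default_rng(seed)
    chol = linalg.cholesky(np.linalg.inv(precision_true), lower=True)
    L = chol @ rng.standard_normal((k, n))
    labels = rng.integers(0, k, size=p_total)
    X = L[labels] + sigma_obs * rng.standard_normal((p_total, n))
    if gene_ids is None:
        width = len(str(p_total - 1))
        gene_ids = [f"g{i:0{width}d}" for i in range(p_total)]
    return ModuleAssignment(gene_ids, labels, k), L, X


def split_datasets(
    X: np.ndarray,
    gene_ids: list[str],
    setting: tuple[int, int, int],
    n1: int,
    n2: int,
    seed: int | np.random.Generator,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split X's columns into two studies with overlapping gene subsets.

    The OL shared genes are a uniformly random subset; the remaining genes go
    to dataset 1 (D1 of them) and dataset 2 (D2).  Columns are randomly
    permuted, the first n1 become dataset 1 and the next n2 dataset 2.
    """
    p_total, n = X.shape
    ol, d1, d2 = setting
    if ol + d1 + d2 != p_total:
        raise ValueError(f"setting {setting} must sum to p_total={p_total}")
    if n1 + n2 > n:
        raise ValueError(f"n1+n2={n1 + n2} exceeds available samples {n}")
    rng = np.random.default_rng(seed)
    perm_genes = rng.permutation(p_total)
    shared = perm_genes[:ol]
    only1 = perm_genes[ol : ol + d1]
    only2 = perm_genes[ol + d1 :]
    cols = rng.permutation(n)
    cols1, cols2 = cols[:n1], cols[n1 : n1 + n2]
    rows1 = np.sort(np.concatenate([shared, only1]))
    rows2 = np.sort(np.concatenate([shared, only2]))
    samples = [f"s{j:03d}" for j in range(n)]
    ds1 = ExpressionDataset(
        [gene_ids[i] for i in rows1],
        [samples[j] for j in cols1],
        X[np.ix_(rows1, cols1)],
    )
    ds2 = ExpressionDataset(
        [gene_ids[i] for i in rows2],
        [samples[j] for j in cols2],
        X[np.ix_(rows2, cols2)],
    )
    return ds1, ds2


def make_instantiation(
    config: SimulationConfig, seed: int | np.random.Generator
) -> SyntheticTruth:
    """Generate one complete ground-truth instantiation.

    Training data X (n1+n2 samples) is split into the two studies; the test
    matrix draws fresh latents and noise from the same (Z, Sigma_L, sigma).
    """
    rng = np.random.default_rng(seed)
    G, precision, eps = sample_precision(config.k, config.d, rng)
    n_train = config.n1 + config.n2
    Z_true, _, X = sample_model(
        precision, config.p_total, n_train, config.sigma_obs, rng
    )
    ds1, ds2 = split_datasets(
        X, Z_true.gene_ids, config.setting, config.n1, config.n2, rng
    )
    chol = linalg.cholesky(np.linalg.inv(precision), lower=True)
    L_test = chol @ rng.standard_normal((config.k, config.n_test))
    Y = L_test[Z_true.labels] + config.sigma_obs * rng.standard_normal(
        (config.p_total, config.n_test)
    )
    return SyntheticTruth(
        G=G,
        precision_true=precision,
        epsilon=eps,
        density=config.d,
        Z_true=Z_true,
        sigma_obs=config.sigma_obs,
        dataset1=ds1,
        dataset2=ds2,
        test_Y=Y,
        setting=config.setting,
        config=config,
    )
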