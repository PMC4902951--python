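"""The INSPIRE model and its MAP coordinate-ascent learner.

Model
-----
Each of Q expression datasets X^q (p_q genes x n_q samples) is a noisy view
of k latent module activities L^q (k x n_q):

    L^q ~ N(0, Sigma_L),        X^q | Z^q L^q, sigma^2 ~ N(Z^q L^q, sigma^2 I),

where Z is a hard p_T x k gene-to-module indicator (one module per gene) and
Theta_L = Sigma_L^{-1} is a sparse k x k precision matrix shared across
datasets; its nonzero off-diagonals are the conditional-dependence edges
among modules.  The joint log posterior, with an L1 prior on Theta_L's
off-diagonals, is maximized by coordinate ascent over (L, Z, Theta_L):

* L-step: for each dataset, the exact maximizer of the strictly concave
  latent subproblem solves ``(diag(m^q) + sigma^2 Theta) L^q = Z^q' X^q``
  where m^q_c counts dataset-q genes in module c.
* Z-step: each gene goes to the module whose latent trajectory is nearest in
  Euclidean distance over the concatenation of all samples from the datasets
  that measured it (ties -> lowest module index).
* Theta-step: graphical lasso on S_L = (1/n_T) sum_q L^q L^q'.

Each step is an exact coordinate maximizer of the tracked objective

    (n_T/2) [logdet Theta - tr(S_L Theta) - lam * sum_{j != j'} |Theta_jj'|]
    - (1/(2 sigma^2)) sum_q ||X^q - Z^q L^q||_F^2,

so ascent is monotone.  Note the penalty is scaled by n_T/2 relative to the
bare glasso objective solved in the Theta-step: lam is therefore on the
conventional graphical-lasso scale and does not need rescaling with sample
size.

The three published single-dataset adaptations are exposed as ``mode``:
``single_dataset`` (dataset 1 only), ``imputed`` (iterative-PCA-completed
matrix as one dataset), and ``intersection_knn`` (fit on the overlap genes,
then nearest-latent assignment of the rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .datamodel import ExpressionDataset, StudyCollection, build_collection

__all__ = [
    "ModuleAssignment",
    "LatentFeatures",
    "ModulePrecision",
    "InspireModel",
    "update_latents",
    "coordinate_sweep_latents",
    "update_assignments",
    "update_precision",
    "objective",
    "fit",
    "assign_leftover",
]

MODES = ("joint", "single_dataset", "intersection_knn", "imputed")

# A fit whose precision magnitudes explode past this cap has entered the
# weak-penalty degeneracy (a latent variance collapsing toward zero) and is
# aborted; no healthy fit at this model scale comes near it.
THETA_CAP = 1e3


@dataclass
class ModuleAssignment:
    """Hard assignment of each gene to exactly one of k modules."""

    gene_ids: list[str]
    labels: np.ndarray  # (p,) ints in [0, k)
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.shape[0] != len(self.gene_ids):
            raise ValueError("labels must be one module index per gene")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("module labels out of range")

    @property
    def indicator(self) -> np.ndarray:
        """Binary p x k indicator Z (each row sums to 1)."""
        Z = np.zeros((self.labels.shape[0], self.k))
        Z[np.arange(self.labels.shape[0]), self.labels] = 1.0
        return Z

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def restrict(self, genes: list[str]) -> "ModuleAssignment":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ModuleAssignment(list(genes), self.labels[rows], self.k)


@dataclass
class LatentFeatures:
    """Per-dataset latent module activities, one k x n_q matrix per dataset."""

    per_dataset: list[np.ndarray]

    def __post_init__(self) -> None:
        ks = {m.shape[0] for m in self.per_dataset}
        if len(ks) > 1:
            raise ValueError("latent row counts differ across datasets")
        for m in self.per_dataset:
            if not np.all(np.isfinite(m)):
                raise ValueError("non-finite latent values")

    @property
    def k(self) -> int:
        return self.per_dataset[0].shape[0]

    def empirical_covariance(self) -> np.ndarray:
        """S_L = (1/n_T) sum_q L^q L^q'."""
        n_total = sum(m.shape[1] for m in self.per_dataset)
        S = sum(m @ m.T for m in self.per_dataset)
        return S / n_total


@dataclass
class ModulePrecision:
    """Sparse positive-definite module precision Theta_L with its inputs."""

    theta: np.ndarray
    empirical_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.allclose(self.theta, self.theta.T, atol=1e-8):
            raise ValueError("precision matrix must be symmetric")
        w = np.linalg.eigvalsh(self.theta)
        if w.min() <= 0:
            raise ValueError(f"precision not positive definite (min eig {w.min():.3g})")

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.theta)

    def edges(self, tol: float = 1e-8) -> np.ndarray:
        """Boolean k x k matrix of off-diagonal conditional-dependence edges."""
        A = np.abs(self.theta) > tol
        np.fill_diagonal(A, False)
        return A


@dataclass
class InspireModel:
    """A fitted model: assignment, precision, latents and hyperparameters."""

    assignment: ModuleAssignment
    precision: ModulePrecision
    latents: LatentFeatures
    sigma: float
    lam: float
    k: int
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    mode: str = "joint"
    n_iter: int = 0
    degenerate: bool = False

    @property
    def k_effective(self) -> int:
        return int(np.count_nonzero(self.assignment.module_sizes()))


# ---------------------------------------------------------------------------
# coordinate updates


def update_latents(
    collection: StudyCollection,
    assignment: ModuleAssignment,
    theta: np.ndarray,
    sigma: float,
) -> LatentFeatures:
    """Exact L-step: solve the latent linear system per dataset."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = assignment.k
    out = []
    for q, ds in enumerate(collection.datasets):
        labels_q = assignment.labels[collection.dataset_rows[q]]
        out.append(_solve_latents(ds.values, labels_q, k, theta, sigma))
    return LatentFeatures(out)


def _solve_latents(
    X: np.ndarray, labels: np.ndarray, k: int, theta: np.ndarray, sigma: float
) -> np.ndarray:
    m = np.bincount(labels, minlength=k).astype(float)
    B = np.zeros((k, X.shape[1]))
    np.add.at(B, labels, X)
    A = sigma**2 * theta + np.diag(m)
    try:
        return linalg.solve(A, B, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
        raise RuntimeError("singular latent system; is theta positive definite?") from exc


def coordinate_sweep_latents(
    collection: StudyCollection,
    assignment: ModuleAssignment,
    theta: np.ndarray,
    sigma: float,
    n_sweeps: int = 500,
    init: LatentFeatures | None = None,
) -> LatentFeatures:
    """L-step by cyclic per-module fixed-point sweeps.

    The per-coordinate rule
    ``L_c = (Z_c' X - sigma^2 sum_{i != c} Theta_ic L_i) / (m_c + sigma^2 Theta_cc)``
    converges to the same maximizer the linear solve returns; kept as an
    independent route for cross-checking, not the default.
    """
    k = assignment.k
    out = []
    for q, ds in enumerate(collection.datasets):
        labels = assignment.labels[collection.dataset_rows[q]]
        m = np.bincount(labels, minlength=k).astype(float)
        B = np.zeros((k, ds.n_samples))
        np.add.at(B, labels, ds.values)
        L = np.zeros((k, ds.n_samples)) if init is None else init.per_dataset[q].copy()
        s2 = sigma**2
        for _ in range(n_sweeps):
            for c in range(k):
                cross = s2 * (theta[c] @ L - theta[c, c] * L[c])
                L[c] = (B[c] - cross) / (m[c] + s2 * theta[c, c])
        out.append(L)
    return LatentFeatures(out)


def update_assignments(
    collection: StudyCollection, latents: LatentFeatures
) -> ModuleAssignment:
    """Z-step: nearest latent over each gene's concatenated samples.

    A gene measured in several datasets is scored on all of its samples
    jointly; ties break to the lowest module index.
    """
    dist = _distance_matrix(collection, latents)
    labels = np.argmin(dist, axis=1)  # argmin takes the lowest index on ties
    return ModuleAssignment(list(collection.universe), labels, latents.k)


def update_precision(
    latents: LatentFeatures,
    lam: float,
    n_total: int | None = None,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> ModulePrecision:
    """Theta-step: graphical lasso on the empirical latent covariance.

    Maximizes ``logdet Theta - tr((S_L + ridge I) Theta) - lam sum_{j!=j'}
    |Theta_jj'|`` over positive-definite Theta (diagonal unpenalized).  With
    ``ridge=0`` this is the plain penalized MLE; the fitting loop passes a
    small positive ridge (an exponential prior on the precision diagonal)
    because the joint MAP is otherwise unbounded when a module's latent
    variance collapses toward zero.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if n_total is None:
        n_total = sum(m.shape[1] for m in latents.per_dataset)
    S = sum(m @ m.T for m in latents.per_dataset) / n_total
    if ridge:
        S = S + ridge * np.eye(S.shape[0])
    return graphical_lasso_precision(S, lam, max_iter=max_iter)


def graphical_lasso_precision(
    S: np.ndarray, lam: float, max_iter: int = 100
) -> ModulePrecision:
    # Tight tolerances: the outer coordinate ascent relies on this step being
    # an (effectively) exact maximizer, otherwise monotonicity breaks.
    # A weakly penalized fit can drive a latent direction's variance toward
    # zero (the joint MAP degenerates as lam -> 0); when the solver rejects
    # the near-singular covariance, retry on a minimally ridge-stabilized S.
    ridge_scale = float(np.trace(S)) / max(S.shape[0], 1)
    last_exc: Exception | None = None
    for delta in (0.0, 1e-6, 1e-4, 1e-2):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = _sk_graphical_lasso(
                    S + delta * ridge_scale * np.eye(S.shape[0]),
                    alpha=lam,
                    max_iter=max_iter,
                    tol=1e-8,
                    enet_tol=1e-10,
                )
            theta = 0.5 * (theta + theta.T)
            w = np.linalg.eigvalsh(theta)
            if not np.all(np.isfinite(theta)) or w.min() <= 0:
                # solver silently returned a non-PD matrix: same failure mode
                last_exc = FloatingPointError(
                    f"non-PD graphical lasso output (min eig {w.min():.3g})"
                )
                continue
            if delta > 0:
                warnings.warn(
                    f"graphical lasso needed a ridge of {delta:.0e} on the "
                    f"latent covariance (lam={lam:.3g})",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return ModulePrecision(theta, empirical_cov=S)
        except FloatingPointError as exc:
            last_exc = exc
    raise RuntimeError(
        f"graphical lasso failed to converge (lam={lam:.3g}, "
        f"cond(S)={np.linalg.cond(S):.3g})"
    ) from last_exc


def objective(
    collection: StudyCollection,
    assignment: ModuleAssignment,
    latents: LatentFeatures,
    theta: np.ndarray,
    sigma: float,
    lam: float,
    ridge: float = 0.0,
) -> float:
    """The tracked MAP objective (additive constants dropped).

    ``(n_T/2)[logdet T - tr((S_L + ridge I) T) - lam sum_offdiag |T|]
    - (1/(2 sigma^2)) sum_q ||X^q - Z^q L^q||_F^2``

    The ridge term is the log-density of the precision-diagonal prior used
    by :func:`fit`; with ``ridge=0`` this is the bare coordinate-ascent
    objective.
    """
    n_total = collection.n_total
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("theta must be positive definite")
    S = latents.empirical_covariance()
    penalty = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    val = 0.5 * n_total * (
        logdet - np.trace(S @ theta) - ridge * np.trace(theta) - lam * penalty
    )
    recon = 0.0
    for q, ds in enumerate(collection.datasets):
        labels = assignment.labels[collection.dataset_rows[q]]
        recon += ((ds.values - latents.per_dataset[q][labels]) ** 2).sum()
    return float(val - recon / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# the outer loop


def _reseed_empty_modules(
    collection: StudyCollection,
    assignment: ModuleAssignment,
    latents: LatentFeatures,
    retired: np.ndarray,
) -> tuple[ModuleAssignment, list[int]]:
    """Move the worst-reconstructed gene into each empty, non-retired module."""
    sizes = assignment.module_sizes()
    empty = [c for c in range(assignment.k) if sizes[c] == 0 and not retired[c]]
    if not empty:
        return assignment, []
    # current per-gene reconstruction error over the datasets containing it
    err = np.zeros(collection.p_total)
    for q, ds in enumerate(collection.datasets):
        labels = assignment.labels[collection.dataset_rows[q]]
        resid = ds.values - latents.per_dataset[q][labels]
        err[collection.dataset_rows[q]] += (resid**2).sum(axis=1)
    labels = assignment.labels.copy()
    moved = []
    for c in empty:
        g = int(np.argmax(err))
        if sizes[labels[g]] <= 1:
            err[g] = -np.inf
            g = int(np.argmax(err))
        labels[g] = c
        err[g] = -np.inf
        moved.append(c)
    return ModuleAssignment(assignment.gene_ids, labels, assignment.k), moved


def _distance_matrix(
    collection: StudyCollection, latents: LatentFeatures
) -> np.ndarray:
    """Per-gene squared distance to every module latent, accumulated over the
    datasets measuring the gene (the quantity the Z-step minimizes)."""
    k = latents.k
    dist = np.zeros((collection.p_total, k))
    for q, ds in enumerate(collection.datasets):
        L = latents.per_dataset[q]
        X = ds.values
        d_q = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ L.T
            + (L**2).sum(axis=1)[None, :]
        )
        dist[collection.dataset_rows[q]] += d_q
    return dist


def _guarded_assignment_step(
    collection: StudyCollection,
    previous: ModuleAssignment,
    latents: LatentFeatures,
) -> ModuleAssignment:
    """Z-step that never decreases the objective and never empties a module.

    The unconstrained argmin assignment is taken first.  If it empties a
    module, the cheapest gene (smallest reconstruction-cost increase, from a
    donor module that keeps at least one gene) is moved into each emptied
    module; if even the repaired assignment is worse than keeping the
    previous one, the previous assignment is retained.  Keeping the previous
    assignment is always a valid (non-decreasing) coordinate move, so ascent
    is preserved.
    """
    k = latents.k
    dist = _distance_matrix(collection, latents)
    labels = np.argmin(dist, axis=1)  # ties -> lowest index
    sizes = np.bincount(labels, minlength=k)
    if (sizes > 0).all():
        return ModuleAssignment(list(collection.universe), labels, k)
    base_cost = dist[np.arange(len(labels)), labels]
    for c in np.flatnonzero(sizes == 0):
        penalty = dist[:, c] - base_cost
        order = np.argsort(penalty)
        for g in order:
            if sizes[labels[g]] > 1:
                sizes[labels[g]] -= 1
                labels[g] = c
                sizes[c] += 1
                base_cost[g] = dist[g, c]
                break
    repaired_cost = dist[np.arange(len(labels)), labels].sum()
    prev_cost = dist[np.arange(len(labels)), previous.labels].sum()
    if repaired_cost > prev_cost:
        return previous
    return ModuleAssignment(list(collection.universe), labels, k)


def fit(
    collection: StudyCollection,
    k: int,
    lam: float,
    sigma: float = 1.0,
    init: ModuleAssignment | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    mode: str = "joint",
    seed: int | None = None,
    impute_rank: int = 5,
    prior_ridge: float = 1e-3,
) -> InspireModel:
    """Fit the model by coordinate ascent (L -> Z -> L -> Theta per cycle).

    Parameters
    ----------
    init : ModuleAssignment, optional
        Initial gene-to-module assignment over the fitted universe.  When
        omitted, k-means on the iterative-PCA-imputed matrix provides it
        (``seed`` then controls the restarts).
    mode : str
        ``joint`` fits all datasets; ``single_dataset`` uses dataset 1 only;
        ``imputed`` completes the merged matrix and fits it as one dataset;
        ``intersection_knn`` fits the shared genes, then assigns the rest to
        the nearest latent.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "joint":
        return _fit_coordinate(
            collection, k, lam, sigma, init, tol, max_iter, mode, seed,
            impute_rank, prior_ridge,
        )
    if mode == "single_dataset":
        sub = build_collection([collection.datasets[0]])
        if init is not None:
            init = init.restrict(sub.universe)
        return _fit_coordinate(
            sub, k, lam, sigma, init, tol, max_iter, mode, seed,
            impute_rank, prior_ridge,
        )
    if mode == "imputed":
        from .initialize import iterative_pca_impute  # lazy: avoids import cycle

        imputed = iterative_pca_impute(collection, n_components=impute_rank)
        ds = ExpressionDataset(
            list(collection.universe),
            [s for d in collection.datasets for s in d.sample_ids],
            imputed.values,
            standardized=False,
        )
        from .datamodel import zscore_genes

        sub = build_collection([zscore_genes(ds)])
        if init is not None:
            init = init.restrict(sub.universe)
        return _fit_coordinate(
            sub, k, lam, sigma, init, tol, max_iter, mode, seed,
            impute_rank, prior_ridge,
        )
    # intersection_knn
    overlap = [
        g
        for g, row in zip(collection.universe, collection.membership)
        if row.all()
    ]
    if not overlap:
        raise ValueError("intersection mode needs at least one shared gene")
    sub = build_collection([ds.subset_genes(overlap) for ds in collection.datasets])
    if init is not None:
        init = init.restrict(sub.universe)
    model = _fit_coordinate(
        sub, k, lam, sigma, init, tol, max_iter, mode, seed,
        impute_rank, prior_ridge,
    )
    leftover = [g for g in collection.universe if g not in set(overlap)]
    full_assignment = assign_leftover(model, collection, leftover)
    model.assignment = full_assignment
    return model


def _fit_coordinate(
    collection: StudyCollection,
    k: int,
    lam: float,
    sigma: float,
    init: ModuleAssignment | None,
    tol: float,
    max_iter: int,
    mode: str,
    seed: int | None,
    impute_rank: int,
    ridge: float = 1e-3,
) -> InspireModel:
    if init is None:
        from .initialize import default_init  # lazy: avoids import cycle

        init = default_init(collection, k, seed=seed, impute_rank=impute_rank)
    if list(init.gene_ids) != list(collection.universe):
        init = init.restrict(collection.universe)
    if init.k != k:
        raise ValueError(f"init has k={init.k}, expected {k}")

    assignment = init
    theta = np.eye(k)
    if (assignment.module_sizes() == 0).any():
        # repair an init that leaves modules empty (e.g. an assignment
        # restricted to a gene subset) before ascent bookkeeping starts
        latents0 = update_latents(collection, assignment, theta, sigma)
        assignment, _ = _reseed_empty_modules(
            collection, assignment, latents0, np.zeros(k, dtype=bool)
        )
    trace: list[float] = []
    prev = -np.inf
    converged = False
    degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        latents = update_latents(collection, assignment, theta, sigma)
        trace.append(
            objective(collection, assignment, latents, theta, sigma, lam, ridge)
        )
        assignment = _guarded_assignment_step(collection, assignment, latents)
        trace.append(
            objective(collection, assignment, latents, theta, sigma, lam, ridge)
        )
        latents = update_latents(collection, assignment, theta, sigma)
        trace.append(
            objective(collection, assignment, latents, theta, sigma, lam, ridge)
        )
        # Guard against the weak-penalty degeneracy: the MAP objective is
        # unbounded as a latent direction's variance collapses to zero, so a
        # numerically singular S_L means the iteration has diverged.  Stop
        # and return the current state (CV scoring will reject such fits).
        w = np.linalg.eigvalsh(latents.empirical_covariance())
        if lam < 1e-2 and w.min() < 1e-3 * max(w.max(), 1e-12):
            degenerate = True
            warnings.warn(
                f"latent covariance collapsed (lam={lam:.3g}); stopping early",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        try:
            precision = update_precision(
                latents, lam, n_total=collection.n_total, ridge=ridge
            )
        except RuntimeError:
            # solver rejected the near-singular covariance: same degeneracy,
            # caught slightly later; keep the last valid precision
            degenerate = True
            warnings.warn(
                f"precision step failed (lam={lam:.3g}); stopping early",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        if np.abs(precision.theta).max() > THETA_CAP:
            degenerate = True
            warnings.warn(
                f"precision magnitudes exploded (lam={lam:.3g}); stopping early",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        current = objective(
            collection, assignment, latents, precision.theta, sigma, lam, ridge
        )
        # Self-audit: an exact Theta-step cannot decrease the objective, so a
        # decrease certifies the solver stalled on a near-degenerate problem.
        if current < trace[-1] - 1e-6:
            degenerate = True
            warnings.warn(
                f"precision step stalled (lam={lam:.3g}); stopping early",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        theta = precision.theta
        trace.append(current)
        if np.isfinite(prev) and abs(current - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = current

    # leave latents at the exact maximizer for the final (Z, Theta), so
    # post-hoc feature extraction reproduces the stored latents exactly
    latents = update_latents(collection, assignment, theta, sigma)

    if int(np.count_nonzero(assignment.module_sizes() == 0)):
        warnings.warn(
            f"{int(np.count_nonzero(assignment.module_sizes() == 0))} module(s) "
            "ended empty; k_effective is below k",
            RuntimeWarning,
            stacklevel=2,
        )
    return InspireModel(
        assignment=assignment,
        precision=ModulePrecision(theta, empirical_cov=latents.empirical_covariance()),
        latents=latents,
        sigma=sigma,
        lam=lam,
        k=k,
        objective_trace=trace,
        converged=converged,
        mode=mode,
        n_iter=it,
        degenerate=degenerate,
    )


def assign_leftover(
    model: InspireModel, collection: StudyCollection, leftover_genes: list[str]
) -> ModuleAssignment:
    """Assign genes outside the fitted universe to their nearest latent.

    Used by ``intersection_knn``: the model was fitted on the shared genes
    only; every remaining gene goes to the module whose latent trajectory is
    closest in Euclidean distance over the samples of the datasets that
    measured the gene.
    """
    fitted = {g: i for i, g in enumerate(model.assignment.gene_ids)}
    uindex = collection.gene_index()
    for g in leftover_genes:
        if g not in uindex:
            raise KeyError(f"leftover gene {g!r} absent from all datasets")
    k = model.k
    labels_map = dict(zip(model.assignment.gene_ids, model.assignment.labels))
    # distances accumulated per leftover gene across the datasets holding it
    left_index = {g: i for i, g in enumerate(leftover_genes)}
    dist = np.full((len(leftover_genes), k), 0.0)
    seen = np.zeros(len(leftover_genes), dtype=bool)
    for q, ds in enumerate(collection.datasets):
        rows = [r for r, g in enumerate(ds.gene_ids) if g in left_index]
        if not rows:
            continue
        # latents for this dataset exist only if the dataset participated in
        # the fit; mode intersection_knn fits all datasets (gene-restricted)
        L = model.latents.per_dataset[q]
        X = ds.values[rows]
        d_q = (
            (X**2).sum(axis=1)[:, None] - 2.0 * X @ L.T + (L**2).sum(axis=1)[None, :]
        )
        idx = [left_index[ds.gene_ids[r]] for r in rows]
        dist[idx] += d_q
        seen[np.array(idx, dtype=int)] = True
    if leftover_genes and not seen.all():
        missing = [g for g, s in zip(leftover_genes, seen) if not s]
        raise KeyError(f"leftover genes with no expression data: {missing[:5]}")
    out_ids = list(model.assignment.gene_ids) + list(leftover_genes)
    out_labels = np.concatenate(
        [model.assignment.labels, np.argmin(dist, axis=1) if leftover_genes else []]
    ).astype(int)
    # reorder to universe order
    order = {g: i for i, g in enumerate(out_ids)}
    universe = collection.universe
    rows = [order[g] for g in universe]
    return ModuleAssignment(list(universe), out_labels[rows], k)
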