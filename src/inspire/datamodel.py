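"""Expression-matrix containers, I/O, standardization, and multi-study alignment.

An :class:`ExpressionDataset` holds one study's genes x samples matrix.  A
:class:`StudyCollection` aligns Q such datasets over the union of their gene
identifiers (the "universe"), recording which dataset measured which gene.
Datasets may cover different, partially overlapping gene sets -- e.g. two
microarray platforms -- which is the situation the joint learner is built for.

Gene identifiers are matched by exact string equality; any symbol/probe
mapping is upstream preprocessing.  The universe is sorted lexicographically
so downstream module-assignment matrices have a reproducible row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "StudyCollection",
    "load_expression",
    "write_expression",
    "zscore_genes",
    "build_collection",
]

_MEAN_TOL = 1e-8
_SD_TOL = 1e-6


@dataclass
class ExpressionDataset:
    """One study's expression matrix (genes x samples) with identifiers.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (p, n)
        Expression values; must be finite.
    standardized : bool
        True if every gene row has mean 0 and sample (n-1) standard
        deviation 1 within numerical tolerance; verified on construction.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids):
            raise ValueError(
                f"row count {p} does not match {len(self.gene_ids)} gene IDs"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"column count {n} does not match {len(self.sample_ids)} sample IDs"
            )
        if len(set(self.gene_ids)) != p:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.standardized:
            mu = self.values.mean(axis=1)
            if np.any(np.abs(mu) > _MEAN_TOL):
                raise ValueError("standardized flag set but row means are not ~0")
            if n > 1:
                sd = self.values.std(axis=1, ddof=1)
                if np.any(np.abs(sd - 1.0) > _SD_TOL):
                    raise ValueError(
                        "standardized flag set but row standard deviations are not ~1"
                    )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict to ``genes`` (kept in the given order).

        Row-wise standardization is untouched by taking gene subsets, so the
        flag carries over.
        """
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionDataset(
            list(genes), list(self.sample_ids), self.values[rows], self.standardized
        )

    def subset_samples(self, cols: np.ndarray) -> "ExpressionDataset":
        """Restrict to sample columns ``cols``; the result is unstandardized."""
        cols = np.asarray(cols, dtype=int)
        return ExpressionDataset(
            list(self.gene_ids),
            [self.sample_ids[j] for j in cols],
            self.values[:, cols],
            standardized=False,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen:
            out.append(x)
        seen.add(x)
    return sorted(set(out))


def load_expression(path, delimiter: str = "\t") -> ExpressionDataset:
    """Read a delimited expression matrix (header = sample IDs, col 0 = gene IDs)."""
    frame = pd.read_csv(path, sep=delimiter, index_col=0,
                        float_precision="round_trip")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(frame)
        raise ValueError(f"non-numeric cell at {bad} in {path}") from exc
    if not np.all(np.isfinite(values)):
        bad = tuple(np.argwhere(~np.isfinite(values))[0])
        raise ValueError(
            f"non-finite value at row {frame.index[bad[0]]!r}, "
            f"column {frame.columns[bad[1]]!r} in {path}"
        )
    return ExpressionDataset(
        [str(g) for g in frame.index], [str(s) for s in frame.columns], values
    )


def _first_non_numeric(frame: pd.DataFrame) -> str:
    for j, col in enumerate(frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"row {frame.index[i]!r}, column {col!r}"
    return "unknown position"


def write_expression(ds: ExpressionDataset, path, delimiter: str = "\t") -> None:
    """Write ``ds`` in the same layout :func:`load_expression` reads.

    Uses 17-significant-digit floats so a write/read round trip reproduces
    the matrix bit-for-bit for finite doubles.
    """
    ds.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def zscore_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize every gene row to mean 0, sample (n-1) sd 1.

    Standard practice before any L1-penalized model so the sparsity parameter
    is invariant to per-gene scale.  Zero-variance genes cannot be
    standardized and raise with the offending identifiers.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples per gene to standardize")
    mu = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] <= 0)[0]
    if flat.size:
        names = [ds.gene_ids[i] for i in flat[:10]]
        raise ValueError(f"zero-variance genes cannot be standardized: {names}")
    out = (ds.values - mu) / sd
    return ExpressionDataset(
        list(ds.gene_ids), list(ds.sample_ids), out, standardized=True
    )


@dataclass
class StudyCollection:
    """Q aligned expression datasets over a common gene universe.

    ``universe`` is the lexicographically sorted union of gene IDs across the
    datasets and ``membership[i, q]`` marks whether dataset q measured
    universe gene i.  ``dataset_rows[q]`` maps dataset q's rows into universe
    coordinates: ``universe[dataset_rows[q][r]] == datasets[q].gene_ids[r]``.
    """

    datasets: list[ExpressionDataset]
    universe: list[str] = field(init=False)
    membership: np.ndarray = field(init=False)
    dataset_rows: list[np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        for q, ds in enumerate(self.datasets):
            if not ds.standardized:
                raise ValueError(f"dataset {q} is not standardized")
        all_samples: set[str] = set()
        for q, ds in enumerate(self.datasets):
            clash = all_samples & set(ds.sample_ids)
            if clash:
                raise ValueError(f"sample IDs shared across datasets: {sorted(clash)[:5]}")
            all_samples |= set(ds.sample_ids)
        union: set[str] = set()
        for ds in self.datasets:
            union |= set(ds.gene_ids)
        self.universe = sorted(union)
        uindex = {g: i for i, g in enumerate(self.universe)}
        self.membership = np.zeros((len(self.universe), len(self.datasets)), dtype=bool)
        self.dataset_rows = []
        for q, ds in enumerate(self.datasets):
            rows = np.array([uindex[g] for g in ds.gene_ids], dtype=int)
            self.membership[rows, q] = True
            self.dataset_rows.append(rows)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def p_total(self) -> int:
        return len(self.universe)

    @property
    def n_total(self) -> int:
        return sum(ds.n_samples for ds in self.datasets)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.universe)}


def build_collection(datasets: list[ExpressionDataset]) -> StudyCollection:
    """Align standardized datasets over the union of their gene IDs."""
    return StudyCollection(list(datasets))
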