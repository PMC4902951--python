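import numpy as np
import pytest

from inspire.datamodel import ExpressionDataset, build_collection, zscore_genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, prefix="s", gene_prefix="g", standardize=False):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    ds = ExpressionDataset(
        [f"{gene_prefix}{i:03d}" for i in range(p)],
        [f"{prefix}{j:03d}" for j in range(n)],
        values,
    )
    return zscore_genes(ds) if standardize else ds


@pytest.fixture
def small_collection(rng):
    """Two standardized datasets over partially overlapping genes."""
    X = rng.standard_normal((30, 14))
    ds1 = make_dataset(X[:, :8], prefix="a", standardize=True)
    ds2_raw = make_dataset(X[:20, 8:], prefix="b")
    ds2 = zscore_genes(ds2_raw)
    return build_collection([ds1, ds2])
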