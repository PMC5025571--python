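import numpy as np
import pytest

from countnorm import CountMatrix

TOY_COUNTS = np.array([[1.0, 4.0], [4.0, 16.0], [9.0, 36.0]])


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 genes × 2 samples, columns exactly proportional (1:4).

    Library sizes (14, 56); both pre-normalized columns are
    (1/14, 4/14, 9/14), so every ratio-based factor is hand-checkable.
    """
    return CountMatrix(
        counts=TOY_COUNTS.copy(),
        gene_ids=np.array(["g1", "g2", "g3"], dtype=object),
        sample_ids=np.array(["s1", "s2"], dtype=object),
        conditions=np.array(["c1", "c2"], dtype=object),
    )


def random_matrix(rng, n_genes=50, n_samples=6, conditions=None, zeros=0.0):
    """Small random count matrix for oracle-equivalence tests."""
    counts = rng.integers(1, 500, size=(n_genes, n_samples)).astype(float)
    if zeros:
        mask = rng.random((n_genes, n_samples)) < zeros
        counts[mask] = 0.0
        counts[counts.sum(axis=1) == 0, 0] = 1.0  # keep rows non-degenerate
    if conditions is None:
        conditions = [f"c{j + 1}" for j in range(n_samples)]
    return CountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        sample_ids=np.array([f"s{j}" for j in range(n_samples)], dtype=object),
        conditions=np.array(conditions, dtype=object),
    )
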