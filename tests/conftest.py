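import numpy as np
import pandas as pd
import pytest

from tnbckit import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with known values."""
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """50 genes x 20 samples of Gaussian log2-like values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(7, 1.5, size=(50, 20)),
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{j:03d}" for j in range(20)],
    )
    return ExpressionMatrix(values)


def make_matrix(arr, genes=None, samples=None, meta=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), meta)
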