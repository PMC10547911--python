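import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from scfse import FixtureSpec, generate, normalize_log, filter_zero_genes
from scfse.io import CountMatrix, ExpressionMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 cells x 4 genes with one all-zero gene."""
    values = np.array(
        [
            [1, 0, 2, 0],
            [0, 0, 5, 3],
            [4, 0, 0, 1],
        ]
    )
    return CountMatrix(values, ["c1", "c2", "c3"], ["g1", "g2", "g3", "g4"])


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-structure fixture (seed 0) with its expression matrix."""
    cm, labels, informative = generate(FixtureSpec(seed=0))
    expr = normalize_log(filter_zero_genes(cm))
    return cm, expr, labels, informative


@pytest.fixture
def two_blob_expr() -> ExpressionMatrix:
    """Two tight, well-separated 30-cell blobs in 10 dimensions."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.1, (30, 10))
    b = rng.normal(5.0, 0.1, (30, 10))
    x = np.vstack([a, b])
    return ExpressionMatrix(
        np.abs(x), [f"c{i}" for i in range(60)], [f"g{j}" for j in range(10)]
    )


def random_label_pair(rng: np.random.Generator, n_max: int = 15):
    n = int(rng.integers(2, n_max + 1))
    ku = int(rng.integers(1, min(n, 5) + 1))
    kv = int(rng.integers(1, min(n, 5) + 1))
    return rng.integers(0, ku, n), rng.integers(0, kv, n)
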