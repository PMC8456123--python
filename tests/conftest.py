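import numpy as np
import pytest

from semimpute import ExpressionMatrix, Stage


def make_em(values, stage=Stage.RAW_COUNTS, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"g{i}" for i in range(g)],
        cell_ids or [f"c{j}" for j in range(n)],
        stage=stage,
    )


@pytest.fixture
def em_factory():
    return make_em


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """8 genes x 6 cells of sparse small counts, every gene/cell expressed."""
    vals = rng.poisson(3.0, size=(8, 6)).astype(float)
    vals[rng.random((8, 6)) < 0.3] = 0.0
    vals[0] += 1.0  # keep at least one always-positive gene and cell totals > 0
    return make_em(vals)
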