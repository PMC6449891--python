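import numpy as np
import pytest

from grnfuse.io_formats import EdgeList, ExpressionMatrix, ScoredNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """8 genes x 5 experiments of unstructured noise."""
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(8)],
        experiment_ids=[f"e{j}" for j in range(5)],
        values=rng.normal(size=(8, 5)),
    )


@pytest.fixture
def random_symmetric_net(rng):
    """10-gene symmetric score matrix with values in [0, 1], zero diagonal."""
    raw = rng.uniform(size=(10, 10))
    scores = (raw + raw.T) / 2
    np.fill_diagonal(scores, 0.0)
    return ScoredNetwork(
        gene_ids=[f"g{i}" for i in range(10)],
        scores=scores,
        symmetric=True,
        score_range=(0.0, 1.0),
    )


def make_edges(pairs):
    return EdgeList([(a, b, 1.0) for a, b in pairs])
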