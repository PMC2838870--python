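import numpy as np
import pytest

from diffnet import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_expression(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, gene_ids)


@pytest.fixture
def random_expression(rng):
    def factory(n=30, p=6):
        return make_expression(rng.standard_normal((n, p)))

    return factory
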