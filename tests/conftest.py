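import numpy as np
import pandas as pd
import pytest

from fibsig import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_matrix(values, genes=None, samples=None, mode="intensity"):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), mode=mode
    )


@pytest.fixture
def toy_two_group():
    """4 genes x 4 samples, two groups of two, hand-checkable."""
    x = np.array(
        [
            [1.0, 3.0, 2.0, 4.0],
            [5.0, 5.0, 5.0, 5.0],
            [2.0, 2.0, 0.0, 0.0],
            [1.0, 2.0, 3.0, 4.0],
        ]
    )
    return make_matrix(x), ["s0", "s1"], ["s2", "s3"]
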