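import numpy as np
import pandas as pd
import pytest

from wntsig.expression import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples, hand-set values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0],
             [4.0, 3.0, 2.0, 1.0],
             [5.0, 5.0, 6.0, 7.0]],
            index=["pA", "pB", "pC"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


def make_matrix(values, probes=None, samples=None, is_log2=True):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples), is_log2=is_log2
    )
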