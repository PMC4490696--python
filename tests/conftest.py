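import numpy as np
import pandas as pd
import pytest

from posrnaseq import CountMatrix, default_lignano_design


@pytest.fixture
def design():
    return default_lignano_design()


@pytest.fixture
def toy_counts():
    """3 transcripts × 4 samples with easy column sums."""
    frame = pd.DataFrame(
        {
            "A": [10.0, 80.0, 10.0],
            "B": [5.0, 90.0, 5.0],
            "C": [1.0, 98.0, 1.0],
            "D": [0.5, 99.0, 0.5],
        },
        index=["tx1", "tx2", "tx3"],
    )
    return CountMatrix(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_count_matrix(rng, n_transcripts, samples=("A", "B", "C", "D")):
    """Random non-negative counts with some exact zeros and fractions."""
    values = rng.gamma(0.8, 50.0, size=(n_transcripts, len(samples)))
    values[rng.random(values.shape) < 0.2] = 0.0
    # ensure no all-zero column so totals stay positive
    values[0, :] += 1.0
    ids = [f"t{i}" for i in range(n_transcripts)]
    return CountMatrix(pd.DataFrame(values, index=ids, columns=list(samples)))
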