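import numpy as np
import pandas as pd
import pytest

from demi import Design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_design():
    return Design.two_group(["T0", "T1", "T2", "T3"], ["R0", "R1", "R2", "R3"])


@pytest.fixture
def small_matrix(rng):
    """20 probes x 8 samples, continuous intensities, no structure."""
    cols = ["T0", "T1", "T2", "T3", "R0", "R1", "R2", "R3"]
    values = rng.uniform(4, 12, size=(20, 8))
    return pd.DataFrame(
        values, index=[f"p{i}" for i in range(20)], columns=cols
    )


def rank_row_matrix(rows, m, n):
    """Build a frame whose within-row ranks are exactly the given tuples.

    ``rows``: iterable of (test_ranks, ref_ranks); columns are TEST then
    REFERENCE.  Used to drive the probe classifiers with explicit rank
    configurations.
    """
    data = [list(t) + list(r) for t, r in rows]
    cols = [f"T{i}" for i in range(m)] + [f"R{i}" for i in range(n)]
    return pd.DataFrame(
        np.asarray(data, dtype=float),
        index=[f"p{i}" for i in range(len(data))],
        columns=cols,
    )
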