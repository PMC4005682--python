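"""Relative-rank normalization of per-array signal distributions.

Each array (column) is normalized independently by replacing every raw
intensity with 100 * rank / q, where ranks run 1..q ascending in intensity
and ties receive the average (fractional) rank.  The result lies in
(0, 100]: 0 and 100 correspond to the weakest and strongest signals, a
value of 25 sits at the first quartile of the array, and the column median
is always ~50 regardless of the array's brightness.  Unlike quantile
normalization the transform needs no reference distribution, and unlike
absolute ranks it is independent of the number of probes q.

Every downstream test in this package is rank-based, so any order-
preserving per-column transform of the raw data leaves all calls unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import average_ranks
from .io import validate_probe_matrix


def rank_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw probe x sample matrix to relative ranks in (0, 100].

    Parameters
    ----------
    matrix : DataFrame
        Validated probe x sample intensities (finite, q >= 2 rows).

    Returns
    -------
    DataFrame
        Same shape/index/columns; each column is 100 * fractional-rank / q.
    """
    validate_probe_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    q = values.shape[0]
    ranks = average_ranks(values, axis=0)
    rel = ranks * 100.0 / q  # multiply first: keeps the top rank at exactly 100
    return pd.DataFrame(rel, index=matrix.index, columns=matrix.columns)
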