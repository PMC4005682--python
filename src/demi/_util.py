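"""Internal numeric helpers."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def average_ranks(values: np.ndarray, axis: int) -> np.ndarray:
    """Fractional (average-of-ties) ranks 1..n along an axis.

    Fast path: double argsort gives ordinal ranks; only the slices that
    actually contain ties are re-ranked with the tie-averaging routine.
    Equivalent to ``scipy.stats.rankdata(values, 'average', axis=axis)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    order = np.argsort(values, axis=axis, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    np.put_along_axis(
        ranks, order,
        np.broadcast_to(
            np.arange(1.0, n + 1.0).reshape([-1 if a == axis else 1
                                             for a in range(values.ndim)]),
            values.shape,
        ),
        axis=axis,
    )
    sorted_vals = np.take_along_axis(values, order, axis=axis)
    tied = (np.diff(sorted_vals, axis=axis) == 0).any(axis=axis)
    if np.any(tied):
        idx = np.flatnonzero(np.atleast_1d(tied))
        if values.ndim == 1:
            return rankdata(values, method="average")
        if axis == 0:
            ranks[:, idx] = rankdata(values[:, idx], method="average", axis=0)
        else:
            ranks[idx, :] = rankdata(values[idx, :], method="average", axis=1)
    return ranks
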