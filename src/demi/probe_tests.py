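"""Per-probe classification as up-, down- or unchanged.

Two designs are supported:

* two-group (TEST vs REFERENCE): one-sided exact Wilcoxon-Mann-Whitney
  rank-sum tests per probe, with a full-separation heuristic when either
  group has <= 3 samples (where p < 0.05 is theoretically unobtainable);
* monotonic trend over a numeric covariate: one-sided Kendall-tau tests
  per probe, exact for small tie-free series.

Both tails include the observed statistic (P(W >= w) resp. P(W <= w)), so
a probe lands in the up set H when the TEST rank sum is improbably high and
in the down set L when improbably low.  The exact rank-sum null is built by
dynamic programming over subset rank sums; the exact Kendall null by the
Mahonian (inversion-count) recurrence.  Within-row ties invalidate both
uniform-permutation nulls and those rows fall back to the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, norm

from ._util import average_ranks
from .io import Design, ValidationError, align_design

logger = logging.getLogger("demi")

UP, NONE, DOWN = 1, 0, -1

#: largest m*n for which the exact rank-sum null is used
EXACT_RANKSUM_LIMIT = 400
#: largest tie-free series length for which the exact Kendall null is used
EXACT_KENDALL_LIMIT = 9


# ---------------------------------------------------------------------------
# Exact null distributions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def rank_sum_null(m: int, N: int) -> tuple[np.ndarray, int]:
    """Exact null of the sum of m ranks drawn from {1..N} without replacement.

    Returns ``(counts, total)`` where ``counts[s]`` is the number of
    m-subsets of {1..N} whose ranks sum to s, and ``total = C(N, m)``.
    Dynamic programme over items; counts fit in int64 for every m*n within
    the exact-test regime.
    """
    max_sum = (2 * N - m + 1) * m // 2
    counts = np.zeros((m + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for j in range(1, N + 1):
        for k in range(min(m, j), 0, -1):
            counts[k, j:] += counts[k - 1, : max_sum + 1 - j]
    total = int(counts[m].sum())
    return counts[m], total


def ranksum_pvalues(w: np.ndarray, m: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """One-sided exact p-values P(W >= w) and P(W <= w) for integer rank sums."""
    counts, total = rank_sum_null(m, N)
    cdf = np.cumsum(counts)
    w = np.asarray(w).astype(int)
    p_low = cdf[w] / total
    p_high = (total - np.concatenate(([0], cdf))[w]) / total
    return p_high, p_low


@lru_cache(maxsize=32)
def inversion_counts(n: int) -> tuple[np.ndarray, int]:
    """Mahonian numbers: permutations of n items by inversion count.

    Returns ``(counts, n!)`` with ``counts[d]`` = number of permutations
    with exactly d inversions (coefficients of prod_k (1+x+...+x^{k-1})).
    """
    poly = np.array([1], dtype=float)
    for k in range(2, n + 1):
        poly = np.convolve(poly, np.ones(k))
    total = factorial(n)
    return poly, total


# ---------------------------------------------------------------------------
# Classification container
# ---------------------------------------------------------------------------

@dataclass
class ProbeClassification:
    """Per-probe labels plus the background totals the enrichment step needs.

    ``labels`` is an int8 array over ``probe_ids``: +1 (up, set H),
    -1 (down, set L), 0 (unchanged).  ``p_up``/``p_down`` hold the
    one-sided p-values where a test was computed (NaN under the
    small-sample heuristic, which is a deterministic rule, not a test).
    """

    probe_ids: pd.Index
    labels: np.ndarray
    alpha: float
    mode: str
    p_up: np.ndarray | None = None
    p_down: np.ndarray | None = None
    design: Design | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.probe_ids):
            raise ValidationError("labels and probe_ids length mismatch")

    @property
    def n(self) -> int:
        """Total probes tested (the enrichment background size n)."""
        return len(self.probe_ids)

    @property
    def x_up(self) -> int:
        """|H|, the array-wide number of up-classified probes."""
        return int((self.labels == UP).sum())

    @property
    def x_down(self) -> int:
        """|L|, the array-wide number of down-classified probes."""
        return int((self.labels == DOWN).sum())

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.probe_ids, name="label")

    def swapped(self) -> "ProbeClassification":
        """Relabel up <-> down (e.g. after exchanging TEST and REFERENCE)."""
        return ProbeClassification(
            probe_ids=self.probe_ids,
            labels=-self.labels,
            alpha=self.alpha,
            mode=self.mode,
            p_up=self.p_down,
            p_down=self.p_up,
            design=self.design,
            notes=dict(self.notes),
        )


# ---------------------------------------------------------------------------
# Two-group classification
# ---------------------------------------------------------------------------

def classify_two_group(
    ranks: pd.DataFrame, design: Design, alpha: float = 0.05
) -> ProbeClassification:
    """Classify every probe as up/down/unchanged between TEST and REFERENCE.

    For min(m, n) > 3 a one-sided exact Wilcoxon-Mann-Whitney rank-sum test
    is applied per probe in each direction at level ``alpha`` (exact null
    whenever m*n <= 400 and the row has no ties; tie-corrected normal
    approximation with continuity correction otherwise).  For
    min(m, n) <= 3 the full-separation heuristic is used instead: a probe
    is up only if every TEST value exceeds every REFERENCE value, down only
    in the mirror case — equivalent to the one-sided rank-sum p attaining
    its minimum possible value.

    Parameters
    ----------
    ranks : DataFrame
        Rank-normalized probe x sample matrix (any order-preserving
        per-column transform gives identical output).
    design : Design
        Two-group design; samples must exist in ``ranks``.
    alpha : float
        Per-direction significance level, default 0.05.
    """
    if design.mode != "two_group":
        raise ValidationError("classify_two_group requires a two_group design")
    if not 0 < alpha < 0.5:
        raise ValidationError("alpha must be in (0, 0.5)")
    sub = align_design(ranks, design)
    m, n = len(design.test_samples), len(design.ref_samples)
    values = sub.to_numpy(dtype=float)
    q = values.shape[0]
    labels = np.zeros(q, dtype=np.int8)

    if min(m, n) <= 3:
        test = values[:, :m]
        ref = values[:, m:]
        up = test.min(axis=1) > ref.max(axis=1)
        down = test.max(axis=1) < ref.min(axis=1)
        labels[up] = UP
        labels[down] = DOWN
        return ProbeClassification(
            probe_ids=sub.index,
            labels=labels,
            alpha=alpha,
            mode="two_group_heuristic",
            design=design,
            notes={"m": m, "n": n, "heuristic": True},
        )

    N = m + n
    row_ranks = average_ranks(values, axis=1)
    w = row_ranks[:, :m].sum(axis=1)
    sorted_rows = np.sort(values, axis=1)
    has_ties = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)

    p_up = np.empty(q)
    p_down = np.empty(q)
    exact_ok = m * n <= EXACT_RANKSUM_LIMIT
    if exact_ok:
        clean = ~has_ties
        if clean.any():
            p_up[clean], p_down[clean] = ranksum_pvalues(
                np.rint(w[clean]).astype(int), m, N
            )
        approx_rows = has_ties
    else:
        approx_rows = np.ones(q, dtype=bool)
    if approx_rows.any():
        n_approx = int(approx_rows.sum())
        if exact_ok:
            logger.info(
                "normal approximation with tie correction for %d tied row(s)",
                n_approx,
            )
        p_up[approx_rows], p_down[approx_rows] = _ranksum_normal_approx(
            w[approx_rows], sorted_rows[approx_rows], m, n
        )

    labels[p_up <= alpha] = UP
    labels[p_down <= alpha] = DOWN
    both = (p_up <= alpha) & (p_down <= alpha)
    # at alpha < 0.5 the two one-sided tails cannot both trigger
    assert not both.any(), "probe significant in both directions"
    return ProbeClassification(
        probe_ids=sub.index,
        labels=labels,
        alpha=alpha,
        mode="two_group",
        p_up=p_up,
        p_down=p_down,
        design=design,
        notes={"m": m, "n": n, "exact": exact_ok,
               "approx_rows": int(approx_rows.sum())},
    )


def _ranksum_normal_approx(
    w: np.ndarray, sorted_rows: np.ndarray, m: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected normal approximation for the TEST rank sum.

    ``sorted_rows`` are the sorted combined values per row, used to derive
    the tie-group term sum(t^3 - t).
    """
    N = m + n
    mu = m * (N + 1) / 2.0
    tie_term = np.zeros(len(w))
    if N > 1:
        for i, row in enumerate(sorted_rows):
            _, counts = np.unique(row, return_counts=True)
            tie_term[i] = float((counts**3 - counts).sum())
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_up = (w - mu - 0.5) / sigma
        z_down = (w - mu + 0.5) / sigma
    p_up = np.where(sigma > 0, norm.sf(z_up), 1.0)
    p_down = np.where(sigma > 0, norm.cdf(z_down), 1.0)
    return p_up, p_down


# ---------------------------------------------------------------------------
# Monotonic (Kendall-tau) classification
# ---------------------------------------------------------------------------

def classify_monotonic(
    ranks: pd.DataFrame, design: Design, alpha: float = 0.05
) -> ProbeClassification:
    """Classify probes by monotonic association with a numeric covariate.

    Per probe, Kendall's tau between the normalized signal and the
    covariate is tested one-sidedly in each direction: up when
    P(T >= tau_obs) <= alpha, down when P(T <= tau_obs) <= alpha.  The
    exact uniform-permutation null (Mahonian inversion counts) is used for
    series of <= 9 samples with no ties in either the covariate or the
    probe's values; otherwise tau-b with the tie-corrected normal
    approximation.  Constant probes carry no trend and are never called.
    """
    if design.mode != "monotonic":
        raise ValidationError("classify_monotonic requires a monotonic design")
    if not 0 < alpha < 0.5:
        raise ValidationError("alpha must be in (0, 0.5)")
    sub = align_design(ranks, design)
    cov = design.covariate.loc[list(sub.columns)].to_numpy(dtype=float)
    order = np.argsort(cov, kind="stable")
    x = cov[order]
    values = sub.to_numpy(dtype=float)[:, order]
    q, ns = values.shape

    x_tied = len(np.unique(x)) < ns
    pair_i, pair_j = np.triu_indices(ns, k=1)
    diffs = values[:, pair_j] - values[:, pair_i]
    y_tied = (diffs == 0).any(axis=1)

    p_up = np.empty(q)
    p_down = np.empty(q)
    exact_rows = np.zeros(q, dtype=bool)
    if not x_tied and ns <= EXACT_KENDALL_LIMIT:
        exact_rows = ~y_tied
    if exact_rows.any():
        disc = (diffs[exact_rows] < 0).sum(axis=1)  # inversions vs covariate order
        counts, total = inversion_counts(ns)
        cdf = np.cumsum(counts)
        p_up[exact_rows] = cdf[disc] / total  # P(D <= d) = P(tau >= tau_obs)
        p_down[exact_rows] = (total - np.concatenate(([0.0], cdf))[disc]) / total
    approx_rows = np.flatnonzero(~exact_rows)
    for i in approx_rows:
        y = values[i]
        if np.all(y == y[0]):
            p_up[i] = p_down[i] = 1.0
            continue
        tau, p2 = kendalltau(x, y)
        if not np.isfinite(tau):
            p_up[i] = p_down[i] = 1.0
            continue
        if tau > 0:
            p_up[i], p_down[i] = p2 / 2.0, 1.0 - p2 / 2.0
        elif tau < 0:
            p_up[i], p_down[i] = 1.0 - p2 / 2.0, p2 / 2.0
        else:
            p_up[i] = p_down[i] = 0.5

    labels = np.zeros(q, dtype=np.int8)
    labels[p_up <= alpha] = UP
    labels[p_down <= alpha] = DOWN
    assert not ((p_up <= alpha) & (p_down <= alpha)).any()
    return ProbeClassification(
        probe_ids=sub.index,
        labels=labels,
        alpha=alpha,
        mode="monotonic",
        p_up=p_up,
        p_down=p_down,
        design=design,
        notes={"n_samples": ns, "exact_rows": int(exact_rows.sum())},
    )
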