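"""Differential expression of genomic regions via overlapping windows.

Fixed-width windows (default 0.5 Mbp, 50% overlap) tile each chromosome;
probes are assigned to every window containing their alignment midpoint and
the windows are then scored exactly like any other target by hypergeometric
enrichment, with Benjamini-Yekutieli adjustment by default because
overlapping windows share probes.  This detects phenomena such as
long-range epigenetic silencing, where expression drops coherently across
a multi-gene chromosomal block, without any gene model.

All coordinates are 0-based half-open (BED convention); strand is ignored.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_U, hypergeom_enrichment, test_targets
from .io import ProbeAnnotation, ValidationError
from .probe_tests import ProbeClassification

logger = logging.getLogger("demi")

DEFAULT_WIDTH = 500_000
DEFAULT_OVERLAP = 0.5
DEFAULT_MIN_OVERLAP = 250_000


class GenomicWindow(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_sizes: dict[str, int],
    width: int = DEFAULT_WIDTH,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list[GenomicWindow]:
    """Tile each chromosome with fixed-width windows at the given overlap.

    Window starts run 0, step, 2*step, ... while start < chromosome length,
    with step = width * (1 - overlap_fraction); the final windows are
    truncated at the chromosome end (kept, so effects near telomeres stay
    detectable).  Every interior base is covered by round(1/(1-overlap))
    windows.  Zero-length chromosomes are skipped with a warning.
    """
    if width < 2:
        raise ValidationError("width must be >= 2")
    if not 0 <= overlap_fraction < 1:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    step = width * (1.0 - overlap_fraction)
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValidationError(
            f"width*(1-overlap) must be a positive integer, got {step}"
        )
    step = int(round(step))
    windows: list[GenomicWindow] = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            warnings.warn(f"skipping zero-length chromosome {chrom!r}", stacklevel=2)
            continue
        if length <= width:
            # chromosome shorter than one window: a single clipped window
            windows.append(GenomicWindow(str(chrom), 0, length))
            continue
        for start in range(0, length, step):
            windows.append(GenomicWindow(str(chrom), start, min(start + width, length)))
    return windows


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length in bp) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={0: str, 1: int})
    return dict(zip(df["chrom"], df["length"]))


def assign_probes_to_windows(
    alignments: ProbeAnnotation,
    windows: list[GenomicWindow],
    t: int | None = 1,
) -> ProbeAnnotation:
    """Build a genomic_region annotation mapping probes to covering windows.

    A probe belongs to a window iff its alignment midpoint lies in
    [start, end).  Probes with more than ``t`` distinct alignment loci are
    dropped (same multiplicity semantics as the enrichment t-filter); the
    by-construction membership of a probe in up to round(1/(1-overlap))
    overlapping windows is exempt — that dependency is why BY adjustment is
    the default downstream.  Assignment is order-independent.
    """
    if alignments.alignments is None:
        raise ValidationError("annotation carries no genomic alignments")
    aln = alignments.alignments
    if t is not None:
        loci = alignments.alignment_loci()
        multi = set(loci.index[loci > t])
        if multi:
            logger.info("dropping %d probe(s) with > %d alignment loci",
                        len(multi), t)
            aln = aln[~aln["probe_id"].isin(multi)]
    if not alignments.records.empty:
        no_aln = set(alignments.records["probe_id"]) - set(aln["probe_id"])
        if no_aln:
            warnings.warn(
                f"dropping {len(no_aln)} probe(s) without alignment", stacklevel=2
            )

    by_chrom: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    rows: list[tuple[str, str]] = []
    for chrom, wins in by_chrom.items():
        wins = sorted(wins, key=lambda w: (w.start, w.end))
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        max_width = int((ends - starts).max())
        sub = aln[aln["chrom"] == chrom]
        if sub.empty:
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        idx_right = np.searchsorted(starts, mids, side="right")
        for probe, mid, hi in zip(sub["probe_id"], mids, idx_right):
            j = hi - 1
            while j >= 0 and starts[j] > mid - max_width:
                if starts[j] <= mid < ends[j]:
                    rows.append((probe, wins[j].id))
                j -= 1
    rec = pd.DataFrame(rows, columns=["probe_id", "target_id"])
    rec["target_type"] = "genomic_region"
    return ProbeAnnotation(records=rec)


def windows_diff(
    cls: ProbeClassification,
    window_ann: ProbeAnnotation,
    u: int | None = DEFAULT_U,
    fdr_method: str = "by",
    significance: float = 0.05,
) -> pd.DataFrame:
    """Score every window by probe enrichment (BY adjustment by default).

    Thin wrapper over :func:`demi.enrichment.test_targets` with
    target_type='genomic_region' and the window-overlap multiplicity
    exempted from the t-filter.
    """
    return test_targets(
        cls,
        window_ann,
        u=u,
        t=None,
        fdr_method=fdr_method,
        target_type="genomic_region",
        significance=significance,
    )


def _overlap_bp(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def overlap_candidates(
    windows: list[GenomicWindow],
    significant_ids: set[str] | list[str],
    candidates: pd.DataFrame,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[pd.DataFrame, float]:
    """Match significant windows against candidate regions.

    A candidate (rows of a BED-style frame with chrom/start/end[/name]) is
    *detected* iff some significant window overlaps it by at least
    ``min_overlap`` bp.  The returned enrichment p-value asks whether
    candidate-overlapping windows are over-represented among the
    significant windows (one-sided Fisher's exact test via the
    hypergeometric tail, over the supplied window universe).

    Returns ``(per-candidate frame with detected flag and best overlap,
    enrichment p)``.
    """
    if candidates is None or len(candidates) == 0:
        raise ValidationError("empty candidate region set")
    cand = candidates.copy()
    if "name" not in cand.columns:
        cand["name"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(cand.chrom, cand.start, cand.end)
        ]
    significant_ids = set(significant_ids)
    sig_flags = np.array([w.id in significant_ids for w in windows])

    best = np.zeros(len(cand), dtype=int)
    detected = np.zeros(len(cand), dtype=bool)
    hits_candidate = np.zeros(len(windows), dtype=bool)
    for wi, w in enumerate(windows):
        for ci, row in enumerate(cand.itertuples(index=False)):
            if row.chrom != w.chrom:
                continue
            ov = _overlap_bp(w.start, w.end, row.start, row.end)
            if ov >= min_overlap:
                hits_candidate[wi] = True
                if sig_flags[wi]:
                    detected[ci] = True
                    best[ci] = max(best[ci], ov)
    n = len(windows)
    x = int(sig_flags.sum())
    n_i = int(hits_candidate.sum())
    x_i = int((hits_candidate & sig_flags).sum())
    p = hypergeom_enrichment(x_i, n_i, x, n) if n_i else 1.0
    out = pd.DataFrame({
        "name": cand["name"].to_numpy(),
        "chrom": cand["chrom"].to_numpy(),
        "start": cand["start"].to_numpy(),
        "end": cand["end"].to_numpy(),
        "detected": detected,
        "best_overlap_bp": best,
    })
    return out, float(p)
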