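"""Core data containers and TSV/BED readers and writers.

The probe-level intensity matrix and its rank-normalized counterpart are
plain :class:`pandas.DataFrame` objects (rows = probes, columns = samples);
the functions here validate them on the way in.  Probe-to-target annotation
and the experimental design get small dedicated containers because they
carry invariants (exon records need a parent gene, a two-group design needs
disjoint non-empty sample sets) that a bare frame cannot express.

All genomic intervals are 0-based half-open, BED convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("demi")

TARGET_TYPES = frozenset(
    {"gene", "transcript", "exon", "genomic_region", "gene_set", "custom"}
)

#: Result-table columns, in output order.
RESULT_COLUMNS = [
    "target_id",
    "target_type",
    "direction",
    "probes_total",
    "probes_signif",
    "censored",
    "p_value",
    "fdr",
]


class ValidationError(ValueError):
    """A malformed input file or an inconsistent container."""


# ---------------------------------------------------------------------------
# Probe matrix
# ---------------------------------------------------------------------------

def validate_probe_matrix(matrix: pd.DataFrame, *, name: str = "matrix") -> pd.DataFrame:
    """Check a probe x sample intensity frame and return it unchanged.

    Requires unique probe and sample identifiers, at least two probes and
    one sample, and finite numeric values throughout.
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValidationError(f"{name}: duplicate probe_id {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValidationError(f"{name}: duplicate sample id {dup!r}")
    if matrix.shape[0] < 2:
        raise ValidationError(f"{name}: need at least 2 probes, got {matrix.shape[0]}")
    if matrix.shape[1] < 1:
        raise ValidationError(f"{name}: need at least 1 sample")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(matrix.columns):
            coerced = pd.to_numeric(matrix.iloc[:, j], errors="coerce")
            bad = coerced.isna() & matrix.iloc[:, j].notna() | matrix.iloc[:, j].isna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{name}: non-numeric value {matrix.iat[i, j]!r} at "
                    f"probe {matrix.index[i]!r}, sample {col!r}"
                )
        raise ValidationError(f"{name}: non-numeric values")
    finite = np.isfinite(values)
    if not finite.all():
        i, j = np.argwhere(~finite)[0]
        raise ValidationError(
            f"{name}: non-finite value at probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    return matrix


def read_probe_matrix(path) -> pd.DataFrame:
    """Read a probe x sample TSV (first column probe_id, header = sample ids)."""
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0,
                             float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if matrix.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    matrix = matrix.copy()
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    validate_probe_matrix(matrix, name=str(path))
    return matrix.astype(float)


def write_probe_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a probe x sample frame as TSV with full-precision floats."""
    matrix.to_csv(path, sep="\t", index_label="probe_id", lineterminator="\n",
                  float_format=lambda v: repr(float(v)))  # round-trips exactly


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Many-to-many probe-to-target mapping, optionally with genomic alignments.

    Parameters
    ----------
    records : DataFrame
        Columns ``probe_id``, ``target_id``, ``target_type`` and
        ``parent_gene_id`` (nullable; mandatory for exon records).
        Duplicate (probe, target, type) rows are dropped.
    alignments : DataFrame, optional
        Columns ``chrom``, ``start``, ``end``, ``probe_id`` with 0-based
        half-open probe alignment intervals (from BED input).
    """

    records: pd.DataFrame = field(default_factory=lambda: _empty_records())
    alignments: pd.DataFrame | None = None

    def __post_init__(self):
        rec = self.records.copy()
        if "parent_gene_id" not in rec.columns:
            rec["parent_gene_id"] = pd.NA
        rec = rec[["probe_id", "target_id", "target_type", "parent_gene_id"]]
        for col in ("probe_id", "target_id", "target_type"):
            rec[col] = rec[col].astype(str)
        bad_type = set(rec["target_type"]) - TARGET_TYPES
        if bad_type:
            raise ValidationError(f"unknown target_type(s): {sorted(bad_type)}")
        exon = rec["target_type"] == "exon"
        missing_parent = exon & rec["parent_gene_id"].isna()
        if missing_parent.any():
            tid = rec.loc[missing_parent, "target_id"].iloc[0]
            raise ValidationError(f"exon record {tid!r} lacks parent_gene_id")
        rec = rec.drop_duplicates(["probe_id", "target_id", "target_type"])
        self.records = rec.reset_index(drop=True)
        if self.alignments is not None:
            aln = self.alignments.copy()
            aln = aln[["chrom", "start", "end", "probe_id"]]
            aln["start"] = aln["start"].astype(int)
            aln["end"] = aln["end"].astype(int)
            if (aln["end"] <= aln["start"]).any():
                raise ValidationError("alignment with end <= start")
            self.alignments = aln.reset_index(drop=True)

    @property
    def target_types(self) -> list[str]:
        return sorted(self.records["target_type"].unique())

    def of_type(self, target_type: str) -> pd.DataFrame:
        return self.records[self.records["target_type"] == target_type]

    def multiplicity(self, target_type: str) -> pd.Series:
        """Distinct targets of the given type each probe maps to (>= 1)."""
        rec = self.of_type(target_type)
        return rec.groupby("probe_id")["target_id"].nunique()

    def alignment_loci(self) -> pd.Series:
        """Distinct genomic alignment loci per probe."""
        if self.alignments is None:
            raise ValidationError("annotation carries no genomic alignments")
        return self.alignments.groupby("probe_id").size()


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["probe_id", "target_id", "target_type", "parent_gene_id"]
    )


def read_annotation(path, format: str | None = None) -> ProbeAnnotation:
    """Read probe annotation from TSV (probe->target records) or BED (alignments).

    Format is inferred from the file extension when not given.
    """
    path = str(path)
    if format is None:
        format = "bed" if path.endswith(".bed") else "tsv"
    if format == "tsv":
        rec = pd.read_csv(path, sep="\t", dtype=str)
        required = {"probe_id", "target_id", "target_type"}
        if not required <= set(rec.columns):
            raise ValidationError(
                f"{path}: annotation TSV needs columns {sorted(required)}"
            )
        return ProbeAnnotation(records=rec)
    if format == "bed":
        aln = pd.read_csv(path, sep="\t", header=None, comment="#")
        if aln.shape[1] < 4:
            raise ValidationError(f"{path}: BED needs at least 4 columns")
        aln = aln.iloc[:, :4]
        aln.columns = ["chrom", "start", "end", "probe_id"]
        aln["chrom"] = aln["chrom"].astype(str)
        aln["probe_id"] = aln["probe_id"].astype(str)
        return ProbeAnnotation(alignments=aln)
    raise ValidationError(f"unknown annotation format {format!r}")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+/4+ column BED file of regions (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: BED needs at least 3 columns")
    ncol = min(df.shape[1], 4)
    df = df.iloc[:, :ncol]
    df.columns = ["chrom", "start", "end", "name"][:ncol]
    if "name" not in df.columns:
        df["name"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)
        ]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if df.empty:
        raise ValidationError(f"{path}: empty BED file")
    return df


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Experimental design: two-group (TEST vs REFERENCE) or monotonic trend.

    Two-group mode holds disjoint, non-empty TEST and REFERENCE sample sets;
    monotonic mode holds a numeric per-sample covariate (e.g. hours of
    treatment) with at least four distinct values — below four, no probe can
    ever reach one-sided significance at conventional levels.
    """

    mode: str
    test_samples: tuple[str, ...] = ()
    ref_samples: tuple[str, ...] = ()
    covariate: pd.Series | None = None

    def __post_init__(self):
        if self.mode == "two_group":
            self.test_samples = tuple(str(s) for s in self.test_samples)
            self.ref_samples = tuple(str(s) for s in self.ref_samples)
            if not self.test_samples or not self.ref_samples:
                raise ValidationError("two_group design needs >=1 sample per group")
            overlap = set(self.test_samples) & set(self.ref_samples)
            if overlap:
                raise ValidationError(f"samples in both groups: {sorted(overlap)}")
            if len(set(self.test_samples)) != len(self.test_samples) or len(
                set(self.ref_samples)
            ) != len(self.ref_samples):
                raise ValidationError("duplicate sample id within a group")
        elif self.mode == "monotonic":
            if self.covariate is None:
                raise ValidationError("monotonic design needs a covariate")
            cov = self.covariate.astype(float)
            cov.index = cov.index.astype(str)
            if cov.index.has_duplicates:
                raise ValidationError("duplicate sample id in covariate")
            if cov.nunique() < 4:
                raise ValidationError(
                    "monotonic design needs >= 4 distinct covariate values "
                    f"(got {cov.nunique()}); significance is unattainable below 4"
                )
            self.covariate = cov
        else:
            raise ValidationError(f"unknown design mode {self.mode!r}")

    @property
    def samples(self) -> tuple[str, ...]:
        if self.mode == "two_group":
            return self.test_samples + self.ref_samples
        return tuple(self.covariate.index)

    @classmethod
    def two_group(cls, test, ref) -> "Design":
        return cls(mode="two_group", test_samples=tuple(test), ref_samples=tuple(ref))

    @classmethod
    def monotonic(cls, covariate) -> "Design":
        return cls(mode="monotonic", covariate=pd.Series(covariate))


def read_design(path) -> Design:
    """Read a sample design TSV.

    Columns ``sample_id`` plus either ``group`` (values TEST/REFERENCE,
    case-insensitive) for a two-group design, or numeric ``time`` for a
    monotonic design.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: design TSV needs a sample_id column")
    if "group" in df.columns:
        grp = df["group"].str.upper()
        bad = set(grp) - {"TEST", "REFERENCE"}
        if bad:
            raise ValidationError(f"{path}: unknown group label(s) {sorted(bad)}")
        return Design.two_group(
            test=df.loc[grp == "TEST", "sample_id"],
            ref=df.loc[grp == "REFERENCE", "sample_id"],
        )
    if "time" in df.columns:
        cov = pd.Series(
            pd.to_numeric(df["time"]).to_numpy(), index=df["sample_id"].astype(str)
        )
        return Design.monotonic(cov)
    raise ValidationError(f"{path}: design TSV needs a 'group' or 'time' column")


def align_design(matrix: pd.DataFrame, design: Design) -> pd.DataFrame:
    """Subset matrix columns to the design's samples.

    Samples present in the matrix but absent from the design are dropped
    with a logged warning; design samples missing from the matrix are an
    error.
    """
    missing = [s for s in design.samples if s not in matrix.columns]
    if missing:
        raise ValidationError(f"design samples absent from matrix: {missing}")
    extra = [c for c in matrix.columns if c not in set(design.samples)]
    if extra:
        logger.warning("dropping %d matrix sample(s) absent from design: %s",
                       len(extra), extra)
        warnings.warn(
            f"dropping {len(extra)} matrix sample(s) absent from design",
            stacklevel=2,
        )
    return matrix[list(design.samples)]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path) -> None:
    """Write an enrichment result table as TSV.

    Rows are sorted by (fdr ascending, target_id, direction); output is
    byte-identical for identical input.  An empty table yields a
    header-only file.
    """
    if results is None or len(results) == 0:
        out = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        out = results[RESULT_COLUMNS].copy()
        out = out.sort_values(
            ["fdr", "target_id", "direction"], kind="mergesort"
        ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df
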