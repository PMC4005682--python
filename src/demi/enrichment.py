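"""Target-level differential expression by hypergeometric enrichment.

A target (gene, transcript, exon, gene set or genomic region) is scored by
asking whether classified probes are over-represented among its on-target
probes relative to the array-wide background: with n probes on the array of
which X are classified in a given direction, and n_i on-target probes of
which X_i are classified, the one-sided p-value is the hypergeometric upper
tail P(K >= X_i), K ~ Hypergeom(n, X, n_i) — identical to the one-sided
Fisher's exact test on the 2x2 table
a = X_i, b = X - X_i, c = n_i - X_i, d = n - n_i - (X - X_i).

Two guard rails temper the raw test:

* censoring limit ``u`` — targets with more than u probes have their counts
  scaled down to u probes (floor rounding, which can only lose
  significance), capping the sensitivity that huge probe sets would
  otherwise buy;
* multiplicity limit ``t`` — probes mapping to more than t distinct targets
  are removed from the analysis entirely, numerators and background alike,
  because a differentially expressed multi-target probe inflates several
  X_i at once.

P-values are adjusted per direction by Benjamini-Hochberg, or by the
Benjamini-Yekutieli variant (valid under arbitrary dependency) for target
categories whose probe sets overlap substantially (transcripts, exons,
genomic regions, gene sets).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import RESULT_COLUMNS, ProbeAnnotation, ValidationError
from .probe_tests import DOWN, UP, ProbeClassification

logger = logging.getLogger("demi")

#: target types whose probe sets overlap; BY adjustment under `auto`
DEPENDENT_TYPES = frozenset({"transcript", "exon", "genomic_region", "gene_set"})

DEFAULT_U = 30
DEFAULT_T = 1
SIGNIFICANCE = 0.05


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def hypergeom_enrichment(x_i, n_i, x, n):
    """Upper-tail hypergeometric probability P(K >= x_i).

    K counts classified probes among ``n_i`` draws without replacement from
    a background of ``n`` probes containing ``x`` classified ones.  Accepts
    scalars or arrays; bounds are validated.
    """
    x_i = np.asarray(x_i, dtype=np.int64)
    n_i = np.asarray(n_i, dtype=np.int64)
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(x_i < 0) or np.any(x_i > np.minimum(n_i, x)):
        raise ValidationError("require 0 <= X_i <= min(n_i, X)")
    if np.any(n_i > n) or np.any(x > n) or np.any(n_i < 0):
        raise ValidationError("require n_i <= n and X <= n")
    p = hypergeom.sf(x_i - 1, n, x, n_i)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def censor_counts(x_i: int, n_i: int, u: int) -> tuple[int, int]:
    """Scale (X_i, n_i) down to at most u probes, preserving the proportion.

    Identity when n_i <= u; otherwise (floor(X_i * u / n_i), u).  Floor is
    the conservative rounding: it can only make the enrichment p larger.
    """
    if u < 1:
        raise ValidationError("u must be >= 1")
    if n_i <= u:
        return x_i, n_i
    return (x_i * u) // n_i, u


def _censor_arrays(x_i: np.ndarray, n_i: np.ndarray, u: int | None):
    if u is None:
        return x_i, n_i, np.zeros(len(n_i), dtype=bool)
    if u < 1:
        raise ValidationError("u must be >= 1")
    over = n_i > u
    x_c = np.where(over, (x_i * u) // n_i, x_i)
    n_c = np.where(over, u, n_i)
    return x_c, n_c, over


def adjust_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (``bh``) or Benjamini-Yekutieli (``by``) step-up
    adjusted p-values, order-preserving and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in {"bh", "by"}:
        raise ValidationError(f"unknown FDR method {method!r}")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=sm_method)[1]


def resolve_fdr_method(method: str, target_type: str) -> str:
    """Resolve ``auto`` to BH for genes and BY for overlapping categories."""
    if method == "auto":
        return "by" if target_type in DEPENDENT_TYPES else "bh"
    if method not in {"bh", "by"}:
        raise ValidationError(f"unknown FDR method {method!r}")
    return method


# ---------------------------------------------------------------------------
# Target-level testing
# ---------------------------------------------------------------------------

def test_targets(
    cls: ProbeClassification,
    ann: ProbeAnnotation,
    u: int | None = DEFAULT_U,
    t: int | None = DEFAULT_T,
    fdr_method: str = "auto",
    target_type: str | None = None,
    significance: float = SIGNIFICANCE,
) -> pd.DataFrame:
    """Hypergeometric enrichment of classified probes per target, both tails.

    Probes mapping to more than ``t`` distinct targets of the analyzed type
    are removed from the on-target sets *and* from the background totals.
    Counts of targets larger than ``u`` probes are censored down to u.
    FDR adjustment is applied separately within each direction; ``auto``
    picks BH for genes and BY for overlapping categories.

    Returns a long DataFrame with one row per (target, direction), columns
    ``target_id, target_type, direction, probes_total, probes_signif,
    censored, p_value, fdr, significant`` plus the background ``X``/``n``.
    """
    if t is not None and t < 1:
        raise ValidationError("t must be >= 1")
    if target_type is None:
        types = ann.target_types
        if len(types) != 1:
            raise ValidationError(
                f"annotation holds several target types {types}; pass target_type"
            )
        target_type = types[0]
    rec = ann.of_type(target_type)
    if rec.empty:
        raise ValidationError(f"annotation has no {target_type!r} records")

    known = pd.Index(rec["probe_id"].unique())
    missing = known.difference(cls.probe_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} annotated probe(s) absent from the classification, "
            f"e.g. {missing[0]!r}"
        )

    labels = cls.label_series()
    removed = pd.Index([])
    if t is not None:
        mult = ann.multiplicity(target_type)
        removed = pd.Index(mult.index[mult > t])
        if len(removed):
            rec = rec[~rec["probe_id"].isin(removed)]
    if rec.empty:
        raise ValidationError("no annotated probes remain after the t-filter")

    # background after removing t-filtered probes entirely
    n_bg = cls.n - len(removed)
    removed_labels = labels.loc[removed] if len(removed) else pd.Series(dtype=np.int8)
    x_up = cls.x_up - int((removed_labels == UP).sum())
    x_down = cls.x_down - int((removed_labels == DOWN).sum())

    pos = cls.probe_ids.get_indexer(rec["probe_id"])
    probe_lab = cls.labels[pos]
    codes, target_ids = pd.factorize(rec["target_id"].to_numpy(), sort=True)
    agg = pd.DataFrame(
        {
            "n_i": np.bincount(codes, minlength=len(target_ids)),
            "x_up": np.bincount(codes, weights=(probe_lab == UP),
                                minlength=len(target_ids)).astype(np.int64),
            "x_down": np.bincount(codes, weights=(probe_lab == DOWN),
                                  minlength=len(target_ids)).astype(np.int64),
        },
        index=pd.Index(target_ids, name="target_id"),
    )
    return _score_directions(
        agg, x_up, x_down, n_bg, u, fdr_method, target_type, significance
    )


def _score_directions(
    agg: pd.DataFrame,
    x_up: int,
    x_down: int,
    n_bg: int,
    u: int | None,
    fdr_method: str,
    target_type: str,
    significance: float,
    joint_exon_bg: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score both directions for aggregated per-target counts and adjust FDR.

    ``agg`` must have columns n_i, x_up, x_down indexed by target_id; the
    background is either global (x_up/x_down/n_bg scalars) or per-target
    when ``joint_exon_bg`` supplies columns bg_x_up, bg_x_down, bg_n.
    """
    method = resolve_fdr_method(fdr_method, target_type)
    n_i = agg["n_i"].to_numpy()
    out = []
    for direction, x_col, x_tot_scalar in (
        ("up", "x_up", x_up),
        ("down", "x_down", x_down),
    ):
        x_i = agg[x_col].to_numpy()
        x_i_c, n_i_c, censored = _censor_arrays(x_i, n_i, u)
        if joint_exon_bg is not None:
            bg_x = joint_exon_bg["bg_" + x_col].to_numpy()
            bg_n = joint_exon_bg["bg_n"].to_numpy()
        else:
            bg_x = np.full(len(agg), x_tot_scalar, dtype=np.int64)
            bg_n = np.full(len(agg), n_bg, dtype=np.int64)
        # censoring may not push X_i above the background count
        x_i_c = np.minimum(x_i_c, bg_x)
        p = hypergeom_enrichment(x_i_c, n_i_c, bg_x, bg_n)
        fdr = adjust_fdr(p, method)
        out.append(pd.DataFrame({
            "target_id": agg.index,
            "target_type": target_type,
            "direction": direction,
            "probes_total": n_i,
            "probes_signif": x_i,
            "censored": censored,
            "p_value": np.atleast_1d(p),
            "fdr": fdr,
            "significant": fdr < significance,
            "X": bg_x,
            "n": bg_n,
        }))
    result = pd.concat(out, ignore_index=True)
    result.attrs["fdr_method"] = method
    return result


def test_exons_within_gene(
    cls: ProbeClassification,
    ann: ProbeAnnotation,
    u: int | None = DEFAULT_U,
    t: int | None = DEFAULT_T,
    fdr_method: str = "bh",
    significance: float = SIGNIFICANCE,
) -> pd.DataFrame:
    """Differential exon usage: enrichment against the parent gene's probes.

    Identical machinery to :func:`test_targets`, but each exon's background
    is restricted to its parent gene's probe set (n -> |S_gene|, X ->
    classified probes within the gene), so an exon is flagged only when it
    departs from its own gene's behaviour.  Gene probe sets come from
    ``gene``-type records when the annotation has them (exon probes must
    then be a subset) and otherwise from the union of the gene's exon
    probes.  BH adjustment across all exons jointly, per direction.
    """
    exon = ann.of_type("exon")
    if exon.empty:
        raise ValidationError("annotation has no exon records")
    missing = pd.Index(exon["probe_id"].unique()).difference(cls.probe_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} exon probe(s) absent from the classification"
        )
    if t is not None:
        mult = ann.multiplicity("exon")
        removed = mult.index[mult > t]
        exon = exon[~exon["probe_id"].isin(removed)]
        if exon.empty:
            raise ValidationError("no exon probes remain after the t-filter")

    gene_rec = ann.of_type("gene")
    labels = cls.label_series()
    if not gene_rec.empty:
        gene_probes = {
            g: set(sub["probe_id"]) for g, sub in gene_rec.groupby("target_id")
        }
    else:
        gene_probes = {
            g: set(sub["probe_id"])
            for g, sub in exon.groupby("parent_gene_id")
        }
    bg_rows = {}
    for gene, probes in gene_probes.items():
        if not probes:
            raise ValidationError(f"parent gene {gene!r} has no probes")
        lab = labels.loc[list(probes)]
        bg_rows[gene] = (
            int((lab == UP).sum()), int((lab == DOWN).sum()), len(probes)
        )

    agg_rows, bg_frame_rows = [], []
    for (exon_id, gene), sub in exon.groupby(["target_id", "parent_gene_id"]):
        probes = set(sub["probe_id"])
        if gene not in gene_probes:
            raise ValidationError(f"exon {exon_id!r}: unknown parent gene {gene!r}")
        if not probes <= gene_probes[gene]:
            raise ValidationError(
                f"exon {exon_id!r}: probes are not a subset of gene {gene!r} probes"
            )
        lab = labels.loc[list(probes)]
        agg_rows.append((exon_id, len(probes),
                         int((lab == UP).sum()), int((lab == DOWN).sum())))
        bg_frame_rows.append(bg_rows[gene])
    agg = pd.DataFrame(
        agg_rows, columns=["target_id", "n_i", "x_up", "x_down"]
    ).set_index("target_id")
    bg = pd.DataFrame(
        bg_frame_rows, columns=["bg_x_up", "bg_x_down", "bg_n"], index=agg.index
    )
    return _score_directions(
        agg, 0, 0, 0, u, fdr_method, "exon", significance, joint_exon_bg=bg
    )


def test_gene_sets(
    gene_calls: pd.Series,
    sets: ProbeAnnotation,
    fdr_method: str = "by",
    significance: float = SIGNIFICANCE,
) -> pd.DataFrame:
    """Gene-set (e.g. GO category) enrichment of up-/down-called genes.

    Genes play the role of probes: the universe is every gene in
    ``gene_calls`` (values 'up'/'down'/'none' or +1/0/-1), X the number
    called in a direction, and each set contributes (n_i = genes in the
    set, X_i = called genes in the set).  Sets with no gene in the universe
    are omitted with a warning.  BY adjustment by default — probe sets of
    overlapping categories are strongly dependent.
    """
    calls = gene_calls.copy()
    if calls.dtype == object:
        mapping = {"up": UP, "down": DOWN, "none": 0}
        calls = calls.map(mapping)
        if calls.isna().any():
            raise ValidationError("gene_calls values must be up/down/none")
    calls.index = calls.index.astype(str)
    rec = sets.of_type("gene_set")
    if rec.empty:
        raise ValidationError("annotation has no gene_set records")
    universe = set(calls.index)
    kept, dropped = [], []
    for set_id, sub in rec.groupby("target_id"):
        genes = [g for g in set(sub["probe_id"]) if g in universe]
        if not genes:
            dropped.append(set_id)
            continue
        lab = calls.loc[genes]
        kept.append((set_id, len(genes),
                     int((lab == UP).sum()), int((lab == DOWN).sum())))
    if dropped:
        warnings.warn(
            f"omitting {len(dropped)} gene set(s) with no genes in the universe",
            stacklevel=2,
        )
    if not kept:
        raise ValidationError("no gene set overlaps the gene universe")
    agg = pd.DataFrame(
        kept, columns=["target_id", "n_i", "x_up", "x_down"]
    ).set_index("target_id")
    return _score_directions(
        agg,
        int((calls == UP).sum()),
        int((calls == DOWN).sum()),
        len(calls),
        None,
        fdr_method,
        "gene_set",
        significance,
    )


def significant_targets(results: pd.DataFrame, direction: str | None = None,
                        threshold: float = SIGNIFICANCE) -> pd.DataFrame:
    """Rows with adjusted p below ``threshold``, optionally one direction."""
    out = results[results["fdr"] < threshold]
    if direction is not None:
        out = out[out["direction"] == direction]
    return out.sort_values(["fdr", "target_id"]).reset_index(drop=True)
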