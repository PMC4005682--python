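"""Synthetic microarray experiments and the benchmark evaluator.

The generator emulates a two-group high-density array experiment: ~29
probes per gene (discretized gamma), a hierarchical normal baseline on the
log2 scale (gene mean, probe offset, replicate noise), a chosen number of
differentially expressed genes receiving a +/- log2 fold-change on a
fraction of their probes in every TEST array, and a fraction of the
remaining probes shifted as noise.  A configurable fraction of probes
additionally maps to a second gene, so the multiplicity filter has
something to bite on.  Everything is reproducible from the seed.

The evaluator scores target-level calls against the generated truth with
the confusion-matrix conventions used for reference-panel benchmarking:
a call is a true positive only when the direction agrees with the truth;
metrics are reported per FDR cutoff and as the average over the cutoffs
(0.05, 0.01 by default), with the Matthews correlation coefficient as the
headline balanced summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enrichment import test_targets
from .io import Design, ProbeAnnotation, ValidationError
from .normalization import rank_normalize
from .probe_tests import DOWN, UP, classify_two_group

DEFAULT_CUTOFFS = (0.05, 0.01)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-group experiment.

    Defaults are the benchmark's standard conditions: 45,000 genes,
    ~1.3 million probes, 1,000 differentially expressed genes at a log2
    fold-change of +/-2 applied to 80% of on-target probes, 10% of the
    remaining probes shifted as noise, and N=4 replicates per group.
    """

    genes: int = 45_000
    target_total_probes: int = 1_300_000
    de_genes: int = 1_000
    log2_fc: float = 2.0
    frac_on_target: float = 0.8
    frac_noise: float = 0.1
    replicates: int = 4
    multimap_fraction: float = 0.1
    gene_mean_range: tuple[float, float] = (4.0, 12.0)
    probe_sd: float = 0.5
    replicate_sd: float = 0.25
    probe_count_shape: float = 4.0
    probe_count_clip: tuple[int, int] = (1, 200)
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_on_target", "frac_noise", "multimap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.de_genes > self.genes:
            raise ValidationError("de_genes cannot exceed genes")
        if self.genes < 1 or self.replicates < 1:
            raise ValidationError("genes and replicates must be >= 1")

    def scaled(self, factor: float) -> "SimulationConfig":
        """A proportionally smaller configuration (same rates and effects)."""
        return replace(
            self,
            genes=max(1, int(self.genes * factor)),
            target_total_probes=max(2, int(self.target_total_probes * factor)),
            de_genes=max(0, int(self.de_genes * factor)),
        )


@dataclass
class SimulationOutput:
    """Generated experiment: matrix, annotation, and the ground truth."""

    matrix: pd.DataFrame  # raw log2 intensities, TEST then REFERENCE columns
    annotation: ProbeAnnotation
    design: Design
    truth: pd.Series  # per-gene: 'up' / 'down' / 'null'
    shifted_probes: pd.Series  # per-probe bool: received the on-target shift
    config: SimulationConfig

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]


def simulate_experiment(config: SimulationConfig) -> SimulationOutput:
    """Generate one synthetic two-group experiment from the configuration."""
    rng = np.random.default_rng(config.seed)
    g = config.genes
    mean_probes = config.target_total_probes / g
    lo, hi = config.probe_count_clip
    counts = np.clip(
        np.rint(
            rng.gamma(config.probe_count_shape,
                      mean_probes / config.probe_count_shape, size=g)
        ).astype(int),
        lo, hi,
    )
    q = int(counts.sum())
    gene_of_probe = np.repeat(np.arange(g), counts)

    # second-gene assignments for multimapped probes
    n_multi = int(round(config.multimap_fraction * q))
    multi_probes = rng.choice(q, size=n_multi, replace=False)
    second_gene = rng.integers(0, g, size=n_multi)
    clash = second_gene == gene_of_probe[multi_probes]
    second_gene[clash] = (second_gene[clash] + 1) % g

    n_rep = config.replicates
    n_cols = 2 * n_rep
    gene_mean = rng.uniform(*config.gene_mean_range, size=g)
    baseline = gene_mean[gene_of_probe] + rng.normal(0, config.probe_sd, size=q)
    values = baseline[:, None] + rng.normal(0, config.replicate_sd, size=(q, n_cols))

    # differential genes: sign per gene, shift on a fraction of their probes
    de_idx = rng.choice(g, size=config.de_genes, replace=False)
    de_sign = rng.choice([1, -1], size=config.de_genes)
    truth = np.full(g, 0, dtype=np.int8)
    truth[de_idx] = de_sign
    shifted = np.zeros(q, dtype=bool)
    probe_start = np.concatenate(([0], np.cumsum(counts)))
    for gi, sign in zip(de_idx, de_sign):
        probes = np.arange(probe_start[gi], probe_start[gi + 1])
        k = int(round(config.frac_on_target * len(probes)))
        if k:
            chosen = rng.choice(probes, size=k, replace=False)
            values[chosen, :n_rep] += sign * config.log2_fc
            shifted[chosen] = True

    # noise: same magnitude, random sign, on a fraction of the rest
    rest = np.flatnonzero(~shifted)
    n_noise = int(round(config.frac_noise * len(rest)))
    if n_noise:
        noisy = rng.choice(rest, size=n_noise, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_noise)
        values[noisy, :n_rep] += signs[:, None] * config.log2_fc

    probe_ids = pd.Index([f"p{i}" for i in range(q)], name="probe_id")
    gene_ids = np.array([f"g{i}" for i in range(g)])
    sample_ids = [f"T{i}" for i in range(n_rep)] + [f"R{i}" for i in range(n_rep)]
    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)

    rec = pd.DataFrame({
        "probe_id": np.concatenate([probe_ids.to_numpy(),
                                    probe_ids.to_numpy()[multi_probes]]),
        "target_id": np.concatenate([gene_ids[gene_of_probe],
                                     gene_ids[second_gene]]),
        "target_type": "gene",
    })
    annotation = ProbeAnnotation(records=rec)
    design = Design.two_group(test=sample_ids[:n_rep], ref=sample_ids[n_rep:])
    truth_series = pd.Series(
        np.array(["null", "up", "down"])[np.where(truth == 0, 0,
                                                  np.where(truth == 1, 1, 2))],
        index=gene_ids, name="truth",
    )
    return SimulationOutput(
        matrix=matrix,
        annotation=annotation,
        design=design,
        truth=truth_series,
        shifted_probes=pd.Series(shifted, index=probe_ids, name="shifted"),
        config=config,
    )


def simulate_silenced_block(
    chrom_length: int = 10_000_000,
    block: tuple[int, int] = (4_000_000, 5_000_000),
    n_probes: int = 20_000,
    replicates: int = 4,
    log2_fc: float = 2.0,
    intensity_range: tuple[float, float] = (6.0, 10.0),
    replicate_sd: float = 0.25,
    probe_length: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, ProbeAnnotation, Design, tuple[int, int]]:
    """Synthetic genome with one transcriptionally silenced block.

    Probes tile a single chromosome uniformly; probes whose alignment
    midpoint falls inside ``block`` are down-shifted by ``log2_fc`` in every
    TEST array, emulating long-range epigenetic silencing.  Baselines are
    iid per probe (no gene structure).  Returns
    ``(matrix, annotation-with-alignments, design, block)``.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(
        rng.choice(chrom_length - probe_length, size=n_probes, replace=False)
    )
    mids = starts + probe_length // 2
    in_block = (mids >= block[0]) & (mids < block[1])
    baseline = rng.uniform(*intensity_range, size=n_probes)
    n_cols = 2 * replicates
    values = baseline[:, None] + rng.normal(0, replicate_sd, size=(n_probes, n_cols))
    values[in_block, :replicates] -= log2_fc
    probe_ids = pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id")
    sample_ids = [f"T{i}" for i in range(replicates)] + [
        f"R{i}" for i in range(replicates)
    ]
    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    aln = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + probe_length,
        "probe_id": probe_ids.to_numpy(),
    })
    annotation = ProbeAnnotation(alignments=aln)
    design = Design.two_group(test=sample_ids[:replicates],
                              ref=sample_ids[replicates:])
    return matrix, annotation, design, block


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _confusion(calls: pd.Series, truth: pd.Series) -> dict:
    """Confusion counts for direction-aware calls against the truth.

    ``calls``: per-target 'up'/'down' for significant targets, absent or
    'none' otherwise.  A significant call with the wrong direction (or on a
    null target) is a false positive; false negatives are true targets
    with no significant call.
    """
    called = calls.reindex(truth.index, fill_value="none")
    is_called = called != "none"
    is_true = truth != "null"
    agree = is_called & is_true & (called == truth)
    tp = int(agree.sum())
    fp = int((is_called & ~agree).sum())
    tn = int((~is_called & ~is_true).sum())
    fn = int((~is_called & is_true).sum())
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def _metrics(c: dict) -> dict:
    tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
    pos, neg = tp + fn, tn + fp
    out = dict(c)
    out["TPR"] = tp / pos if pos else 0.0
    out["FPR"] = fp / neg if neg else 0.0
    out["TNR"] = tn / neg if neg else 0.0
    out["FNR"] = fn / pos if pos else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        out["MCC"] = 0.0
        out["mcc_undefined"] = True
    else:
        out["MCC"] = (tp * tn - fp * fn) / math.sqrt(denom)
        out["mcc_undefined"] = False
    return out


def evaluate_calls(
    results: pd.DataFrame,
    truth: pd.Series,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Score enrichment results against the ground truth.

    Per FDR cutoff: TP (called, true, direction agrees), FP (called but
    null or wrong direction), TN, FN, the derived rates and the MCC;
    a final ``mean`` row averages the metrics across cutoffs.  Targets in
    the truth but absent from the results count as not called.
    """
    unknown = set(results["target_id"]) - set(truth.index)
    if unknown:
        raise ValidationError(
            f"{len(unknown)} result target(s) missing from the truth, "
            f"e.g. {sorted(unknown)[0]!r}"
        )
    rows = {}
    for cutoff in cutoffs:
        sig = results[results["fdr"] < cutoff]
        # keep the better-supported direction should both ever pass
        sig = sig.sort_values(["target_id", "fdr"], kind="mergesort")
        calls = sig.drop_duplicates("target_id").set_index("target_id")["direction"]
        rows[cutoff] = _metrics(_confusion(calls, truth))
    report = pd.DataFrame(rows).T
    report.index.name = "cutoff"
    mean = report.mean(axis=0)
    mean["mcc_undefined"] = report["mcc_undefined"].any()
    report.loc["mean"] = mean
    return report


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

def run_single(
    config: SimulationConfig,
    u: int | None,
    t: int | None,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationOutput]:
    """One simulate -> normalize -> classify -> enrich -> evaluate pass."""
    sim = simulate_experiment(config)
    ranks = rank_normalize(sim.matrix)
    cls = classify_two_group(ranks, sim.design, alpha=alpha)
    results = test_targets(cls, sim.annotation, u=u, t=t, fdr_method="auto")
    report = evaluate_calls(results, sim.truth, cutoffs=cutoffs)
    return report, results, sim


def run_benchmark(
    config: SimulationConfig,
    reps: int = 10,
    u: int | None = 30,
    t: int | None = 1,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeat the full pipeline on fresh simulations and aggregate.

    Per-rep seeds are spawned deterministically from ``config.seed``, so an
    identical master seed yields a byte-identical summary.  Returns a frame
    of per-rep cutoff-averaged metrics plus ``mean`` and ``sd`` rows.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(reps) % (2**31)
    rows = []
    for r in range(reps):
        rep_cfg = replace(config, seed=int(child_seeds[r]))
        report, results, sim = run_single(rep_cfg, u=u, t=t,
                                          cutoffs=cutoffs, alpha=alpha)
        row = report.loc["mean"].drop("mcc_undefined").to_dict()
        n_targets = results["target_id"].nunique()
        n_sig = results.loc[results["fdr"] < 0.05, "target_id"].nunique()
        row["significant_fraction"] = n_sig / n_targets if n_targets else 0.0
        row["rep"] = r
        rows.append(row)
    per_rep = pd.DataFrame(rows).set_index("rep")
    summary = per_rep.copy()
    summary.loc["mean"] = per_rep.mean()
    summary.loc["sd"] = per_rep.std(ddof=1) if reps > 1 else 0.0
    summary.attrs["u"] = u
    summary.attrs["t"] = t
    summary.attrs["multimap_fraction"] = config.multimap_fraction
    return summary


# ---------------------------------------------------------------------------
# Power of the enrichment test
# ---------------------------------------------------------------------------

def power_fisher(
    n_i: int,
    p0: float,
    p1: float,
    n: int,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo power of the one-sided enrichment test.

    Draw X_i ~ Binomial(n_i, p1) on-target classified probes against a
    background rate p0 (X = round(p0*n) + X_i classified probes among n),
    and count the fraction of replicates with
    hypergeom_enrichment(X_i, n_i, X, n) <= alpha.  Returns
    ``(power, Monte-Carlo standard error)``.
    """
    from .enrichment import hypergeom_enrichment

    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not 0 <= p0 < p1 <= 1:
        if not 0 <= p0 <= p1 <= 1:
            raise ValidationError("require 0 <= p0 <= p1 <= 1")
    rng = np.random.default_rng(seed)
    x_i = rng.binomial(n_i, p1, size=reps)
    x = int(round(p0 * n)) + x_i
    p = hypergeom_enrichment(x_i, np.full(reps, n_i), x, np.full(reps, n))
    power = float(np.mean(p <= alpha))
    se = math.sqrt(power * (1.0 - power) / reps)
    return power, se
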