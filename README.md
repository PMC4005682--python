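# demi — probe-level differential expression for high-density microarrays

`demi` estimates differential expression (DE) of genes, transcripts,
exons, gene sets and genomic regions directly from probe-level microarray
intensities. Conventional pipelines summarize the dozens of probes
interrogating each target into one probe-set value *before* testing,
discarding replication that is especially valuable when the number of
arrays per group is small. `demi` reverses the order: it tests every
probe, then pools the probe-level verdicts into a target-level estimate.

It is aimed at transcriptomics analysts working with probe-level exports
from high-density arrays (or any assay producing many concurrent
measurements per target), including two-group comparisons at very small
N and time-course designs scored for monotonic response.

## The statistic

1. **Normalize** each array to relative ranks: intensity → `100·r/q`
   (fractional ranks for ties), so 0–100 spans weakest to strongest
   signal and the median is always ≈ 50.
2. **Classify** each probe as up (`H`), down (`L`) or unchanged:
   one-sided exact Wilcoxon–Mann–Whitney rank-sum tests for TEST vs
   REFERENCE designs (with a full-separation heuristic when
   `min(m, n) ≤ 3`, where p < 0.05 is unattainable), or one-sided exact
   Kendall-tau tests against a numeric covariate for monotonic designs.
3. **Score** each target by the enrichment of classified probes among its
   `n_i` on-target probes relative to the array-wide background of `n`
   probes with `X` classified, via the hypergeometric upper tail

   `p = P(K ≥ X_i)`, `K ~ Hypergeom(n, X, n_i)`

   — a one-sided Fisher's exact test on the table `(X_i, X−X_i,
   n_i−X_i, n−n_i−(X−X_i))`. Counts of targets larger than the censoring
   limit `u` (default 30) are scaled down to `u`, and probes mapping to
   more than `t` (default 1) distinct targets are removed from counts
   and background alike. P-values are FDR-adjusted per direction (BH for
   genes; BY for overlapping categories such as transcripts, exons,
   genomic windows, gene sets).

See `docs/methods.md` for the full model, parameter rationale, numerical
details and known limitations.

## Worked example

```python
import numpy as np, pandas as pd
from demi import DEMI, Design, ProbeAnnotation

rng = np.random.default_rng(0)
cols = ["T0", "T1", "T2", "T3", "R0", "R1", "R2", "R3"]
values = rng.uniform(4, 12, size=(60, 1)) + rng.normal(0, 0.25, size=(60, 8))
values[:10, :4] += 2.0       # gene g0 up-regulated in the TEST group
matrix = pd.DataFrame(values, index=[f"p{i}" for i in range(60)], columns=cols)
ann = ProbeAnnotation(records=pd.DataFrame({
    "probe_id": matrix.index,
    "target_id": [f"g{i // 10}" for i in range(60)],
    "target_type": "gene",
}))
design = Design.two_group(cols[:4], cols[4:])
res = DEMI(matrix, ann, design).fit(u=30, t=1)
print(res.summary())
```

prints

```
Probe-level differential expression (hypergeometric enrichment)
================================================================
Design:               two_group
Probe test:           two_group (alpha=0.05)
Probes (background n): 60
  up  (|H|, X_up):    10
  down(|L|, X_down):  17
Targets tested:       6 (gene)
Censoring limit u:    30
Multiplicity limit t: 1
FDR method:           bh
Significant (fdr<0.05): 1 up, 0 down
----------------------------------------------------------------
Top targets:
target_id target_type direction  probes_total  probes_signif  censored  p_value      fdr
       g0        gene        up            10             10     False 1.33e-11 7.96e-11
       g5        gene      down            10              5     False    0.103    0.617
...
```

All 10 of g0's probes are individually significant against a background
of 10 up-classified probes among 60, so the hypergeometric tail is
`P(K ≥ 10) = 1.3e-11` and g0 is the lone significant target. Note the 17
down-classified probes: ranks are a closed scale, so pushing one sixth of
the probes up necessarily displaces others down — per-target enrichment
against the background rate is what keeps those displacements from
becoming calls.

The same interface covers the other designs and categories:
`Design.monotonic(covariate)` scores temporal monotonicity per probe with
Kendall's tau, `fit(exon_within_gene=True)` tests exons against their
parent gene's probes, `test_gene_sets` lifts gene-level calls to
categories, and `make_windows` / `assign_probes_to_windows` /
`windows_diff` score overlapping genomic windows (e.g. long-range
epigenetic silencing) from BED probe alignments.

A CLI mirrors the library:

```sh
demi normalize --in matrix.tsv --out ranks.tsv
demi diff --matrix matrix.tsv --design design.tsv --ann ann.tsv \
          --u 30 --t 1 --fdr auto --out results.tsv
demi monotonic --matrix matrix.tsv --design times.tsv --ann ann.tsv --out r.tsv
demi windows --matrix m.tsv --design d.tsv --bed probes.bed \
             --chrom-sizes sizes.tsv --candidates lres.bed --out w.tsv
demi simulate --config sim.toml --reps 10 --seed 7 --out bench.tsv
demi power --ni 5,10,30,100 --p0 0.1 --p1 0.8
```

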