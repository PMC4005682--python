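"""Hypergeometric enrichment, censoring, multiplicity filter, FDR."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from demi import (
    ProbeAnnotation,
    ValidationError,
    adjust_fdr,
    censor_counts,
    hypergeom_enrichment,
)
from demi import test_exons_within_gene as exons_within_gene
from demi import test_gene_sets as gene_set_enrichment
from demi import test_targets as target_enrichment
from demi.probe_tests import ProbeClassification


def exact_tail(x_i, n_i, x, n):
    """Independent oracle: exhaustive tail summation with exact rationals."""
    return float(
        sum(
            Fraction(comb(x, j) * comb(n - x, n_i - j), comb(n, n_i))
            for j in range(x_i, min(n_i, x) + 1)
        )
    )


def make_classification(labels, probe_ids=None):
    labels = np.asarray(labels, dtype=np.int8)
    if probe_ids is None:
        probe_ids = pd.Index([f"p{i}" for i in range(len(labels))])
    return ProbeClassification(probe_ids=probe_ids, labels=labels,
                               alpha=0.05, mode="two_group")


def gene_annotation(mapping):
    rows = [(p, g) for p, genes in mapping.items() for g in genes]
    rec = pd.DataFrame(rows, columns=["probe_id", "target_id"])
    rec["target_type"] = "gene"
    return ProbeAnnotation(records=rec)


class TestHypergeomEnrichment:
    def test_zero_hits_is_one(self):
        assert hypergeom_enrichment(0, 10, 50, 1000) == pytest.approx(1.0)

    def test_all_draws_is_one(self):
        assert hypergeom_enrichment(7, 100, 7, 100) == pytest.approx(1.0)

    def test_example_tail(self):
        assert hypergeom_enrichment(5, 10, 10, 100) == pytest.approx(
            6.7162774826505e-4, rel=1e-10
        )

    def test_bounds_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment(11, 10, 50, 100)
        with pytest.raises(ValidationError):
            hypergeom_enrichment(1, 200, 50, 100)

    def test_matches_fisher_and_tail_oracles(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            x = int(rng.integers(0, n + 1))
            n_i = int(rng.integers(1, n + 1))
            lo = max(0, n_i + x - n)
            x_i = int(rng.integers(lo, min(n_i, x) + 1))
            p = hypergeom_enrichment(x_i, n_i, x, n)
            table = [[x_i, x - x_i], [n_i - x_i, n - n_i - (x - x_i)]]
            _, p_fisher = fisher_exact(table, alternative="greater")
            assert p == pytest.approx(p_fisher, rel=1e-10)
            assert p == pytest.approx(exact_tail(x_i, n_i, x, n), rel=1e-10)

    def test_monotone_in_x_i_and_x(self):
        ps = [hypergeom_enrichment(k, 20, 100, 1000) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        ps_x = [hypergeom_enrichment(5, 20, x, 1000) for x in range(5, 500, 7)]
        assert all(a <= b for a, b in zip(ps_x, ps_x[1:]))


class TestCensoring:
    def test_scales_down(self):
        assert censor_counts(50, 100, 30) == (15, 30)

    def test_identity_when_small(self):
        assert censor_counts(5, 20, 30) == (5, 20)

    def test_censoring_reduces_significance(self):
        n, x = 10**6, 10**5
        p_censored = hypergeom_enrichment(15, 30, x, n)
        p_raw = hypergeom_enrichment(50, 100, x, n)
        assert p_censored > p_raw

    def test_invalid_u(self):
        with pytest.raises(ValidationError):
            censor_counts(1, 2, 0)


class TestAdjustFdr:
    def test_bh_example(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_by_example(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04], "by")
        assert np.allclose(out, [0.04 * 25 / 12] * 4)

    def test_single_p_unchanged_bh(self):
        assert adjust_fdr([0.123], "bh")[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_fdr([0.5, 1.2], "bh")

    @pytest.mark.parametrize("method", ["bh", "by"])
    def test_matches_definitional_step_up_oracle(self, method, rng):
        """Definitional oracle: q_(i) = min_{j>=i} m*c*p_(j)/j, capped at 1."""
        for _ in range(200):
            m = int(rng.integers(1, 13))
            p = rng.uniform(size=m)
            order = np.argsort(p)
            c = sum(1.0 / i for i in range(1, m + 1)) if method == "by" else 1.0
            raw = [m * c * p[order[i]] / (i + 1) for i in range(m)]
            stepped = np.minimum.accumulate(raw[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert np.allclose(adjust_fdr(p, method), expected)

    def test_adjusted_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=30)
        adj = adjust_fdr(p, "bh")
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestTestTargets:
    def test_counts_and_background(self):
        # 10 probes: p0..p3 -> gA (3 up), p4,p5 -> gA+gB (multimapped),
        # p6..p9 unannotated background
        labels = [1, 1, 1, 0, 1, 1, 0, 0, -1, 0]
        cls = make_classification(labels)
        ann = gene_annotation({
            "p0": ["gA"], "p1": ["gA"], "p2": ["gA"], "p3": ["gA"],
            "p4": ["gA", "gB"], "p5": ["gA", "gB"],
        })
        res = target_enrichment(cls, ann, u=None, t=1, fdr_method="bh")
        up = res[(res.target_id == "gA") & (res.direction == "up")].iloc[0]
        # multimapped p4,p5 removed from gA and from the background
        assert up.probes_total == 4 and up.probes_signif == 3
        assert up.n == 8 and up.X == 3
        assert up.p_value == pytest.approx(exact_tail(3, 4, 3, 8), rel=1e-10)
        # gB lost its only probes -> absent
        assert "gB" not in set(res.target_id)

    def test_unclassified_target_never_significant(self):
        cls = make_classification([0, 0, 0, 1, -1, 0])
        ann = gene_annotation({"p0": ["gA"], "p1": ["gA"], "p2": ["gA"]})
        res = target_enrichment(cls, ann, u=None, t=None, fdr_method="bh")
        assert (res.p_value == 1.0).all()
        assert not res.significant.any()

    def test_censored_flag_and_counts(self):
        labels = [1] * 50 + [0] * 150
        cls = make_classification(labels)
        ann = gene_annotation({f"p{i}": ["gA"] for i in range(40)})
        res = target_enrichment(cls, ann, u=30, t=1, fdr_method="bh")
        up = res[(res.direction == "up") & (res.target_id == "gA")].iloc[0]
        assert bool(up.censored)
        assert up.probes_total == 40  # uncensored count reported
        assert up.p_value == pytest.approx(exact_tail(30, 30, 50, 200), rel=1e-9)

    def test_direction_symmetry(self, rng):
        labels = rng.choice([1, 0, -1], size=60, p=[0.2, 0.6, 0.2])
        cls = make_classification(labels)
        ann = gene_annotation({f"p{i}": [f"g{i % 5}"] for i in range(60)})
        a = target_enrichment(cls, ann, u=None, t=None, fdr_method="bh")
        b = target_enrichment(cls.swapped(), ann, u=None, t=None, fdr_method="bh")
        a_up = a[a.direction == "up"].set_index("target_id")
        b_down = b[b.direction == "down"].set_index("target_id")
        assert np.allclose(a_up.p_value, b_down.loc[a_up.index].p_value)

    def test_missing_probe_in_classification_rejected(self):
        cls = make_classification([1, 0])
        ann = gene_annotation({"p0": ["gA"], "p9": ["gA"]})
        with pytest.raises(ValidationError, match="absent"):
            target_enrichment(cls, ann)

    def test_invalid_t_rejected(self):
        cls = make_classification([1, 0])
        ann = gene_annotation({"p0": ["gA"]})
        with pytest.raises(ValidationError):
            target_enrichment(cls, ann, t=0)

    def test_auto_fdr_by_for_dependent_types(self):
        cls = make_classification([1, 0, 0, 0])
        rec = pd.DataFrame({
            "probe_id": ["p0", "p1", "p2", "p3"],
            "target_id": ["t1", "t1", "t2", "t2"],
            "target_type": "transcript",
        })
        res = target_enrichment(cls, ProbeAnnotation(records=rec), fdr_method="auto")
        assert res.attrs["fdr_method"] == "by"


class TestExonWithinGene:
    @staticmethod
    def _exon_ann(gene_probes, exon_probes):
        rows = [(p, "geneA", "gene", None) for p in gene_probes]
        rows += [(p, "ex1", "exon", "geneA") for p in exon_probes]
        rec = pd.DataFrame(
            rows, columns=["probe_id", "target_id", "target_type",
                           "parent_gene_id"]
        )
        return ProbeAnnotation(records=rec)

    def test_reference_example(self):
        # gene: 30 probes, 15 up; exon: 5 probes, all 5 up
        probes = [f"p{i}" for i in range(30)]
        labels = [1] * 15 + [0] * 15
        cls = make_classification(labels, pd.Index(probes))
        ann = self._exon_ann(probes, probes[:5])
        res = exons_within_gene(cls, ann, u=None, t=None)
        up = res[res.direction == "up"].iloc[0]
        expected = comb(15, 5) / comb(30, 5)
        assert up.p_value == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.0210728, rel=1e-4)

    def test_exon_equals_gene_is_one(self):
        probes = [f"p{i}" for i in range(10)]
        cls = make_classification([1] * 4 + [0] * 6, pd.Index(probes))
        ann = self._exon_ann(probes, probes)
        res = exons_within_gene(cls, ann, u=None, t=None)
        assert np.allclose(res.p_value, 1.0)

    def test_gene_without_classified_probes_all_ones(self):
        probes = [f"p{i}" for i in range(12)]
        cls = make_classification([0] * 12, pd.Index(probes))
        ann = self._exon_ann(probes, probes[:3])
        res = exons_within_gene(cls, ann, u=None, t=None)
        assert np.allclose(res.p_value, 1.0)

    def test_exon_not_subset_of_gene_rejected(self):
        probes = [f"p{i}" for i in range(6)]
        cls = make_classification([0] * 7,
                                  pd.Index(probes + ["stray"]))
        rows = [(p, "geneA", "gene", None) for p in probes]
        rows += [("stray", "ex1", "exon", "geneA")]
        ann = ProbeAnnotation(records=pd.DataFrame(
            rows, columns=["probe_id", "target_id", "target_type",
                           "parent_gene_id"]))
        with pytest.raises(ValidationError, match="subset"):
            exons_within_gene(cls, ann, u=None, t=None)


class TestGeneSets:
    @staticmethod
    def _sets(mapping):
        rows = [(g, s) for s, genes in mapping.items() for g in genes]
        rec = pd.DataFrame(rows, columns=["probe_id", "target_id"])
        rec["target_type"] = "gene_set"
        return ProbeAnnotation(records=rec)

    def test_oracle_value(self):
        # universe 1000 genes, 100 up; one set of 10 genes with 5 up
        genes = [f"g{i}" for i in range(1000)]
        calls = pd.Series(["up"] * 100 + ["none"] * 900, index=genes)
        members = genes[:5] + genes[-5:]
        res = gene_set_enrichment(calls, self._sets({"S": members}))
        up = res[res.direction == "up"].iloc[0]
        assert up.p_value == pytest.approx(exact_tail(5, 10, 100, 1000),
                                           rel=1e-10)
        assert up.p_value == pytest.approx(1.5214219e-3, rel=1e-5)

    def test_set_equal_to_universe_is_one(self):
        genes = [f"g{i}" for i in range(50)]
        calls = pd.Series(["up"] * 10 + ["none"] * 40, index=genes)
        res = gene_set_enrichment(calls, self._sets({"S": genes}))
        assert np.allclose(res.p_value, 1.0)

    def test_no_up_genes_all_ones(self):
        genes = [f"g{i}" for i in range(50)]
        calls = pd.Series(["none"] * 50, index=genes)
        res = gene_set_enrichment(calls, self._sets({"S": genes[:5]}))
        assert np.allclose(res[res.direction == "up"].p_value, 1.0)

    def test_disjoint_set_omitted_with_warning(self):
        genes = [f"g{i}" for i in range(20)]
        calls = pd.Series(["up"] * 5 + ["none"] * 15, index=genes)
        sets = self._sets({"S1": genes[:4], "S2": ["zz1", "zz2"]})
        with pytest.warns(UserWarning, match="omitting"):
            res = gene_set_enrichment(calls, sets)
        assert set(res.target_id) == {"S1"}
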