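"""Model / Results interface over the probe-level pipeline.

:class:`DEMI` bundles an intensity matrix, a probe annotation and an
experimental design; :meth:`DEMI.fit` runs normalization, probe
classification and target enrichment and returns a :class:`DEMIResults`
holding the per-target estimates, the probe classification they rest on,
and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import enrichment, io, normalization, probe_tests
from .io import Design, ProbeAnnotation, ValidationError


class DEMI:
    """Probe-level differential expression model.

    Parameters
    ----------
    matrix : DataFrame
        Raw probe x sample intensities (finite; q >= 2).
    annotation : ProbeAnnotation
        Probe-to-target mapping.  Annotation rows for probes absent from
        the matrix are dropped with a warning at fit time.
    design : Design
        Two-group or monotonic design over the matrix's samples.
    target_type : str, optional
        Which annotation category to test; required only when the
        annotation mixes categories.

    Examples
    --------
    >>> model = DEMI(matrix, annotation, Design.two_group(["T1","T2","T3","T4"],
    ...                                                   ["R1","R2","R3","R4"]))
    >>> res = model.fit(u=30, t=1)
    >>> res.significant("up").head()
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        annotation: ProbeAnnotation,
        design: Design,
        target_type: str | None = None,
    ):
        io.validate_probe_matrix(matrix)
        self.matrix = matrix
        self.annotation = annotation
        self.design = design
        if target_type is None:
            types = annotation.target_types
            target_type = types[0] if len(types) == 1 else None
        self.target_type = target_type
        self._ranks: pd.DataFrame | None = None

    @classmethod
    def from_tsv(
        cls,
        matrix_path,
        annotation_path,
        design_path,
        target_type: str | None = None,
    ) -> "DEMI":
        """Build a model from the three standard TSV inputs."""
        return cls(
            io.read_probe_matrix(matrix_path),
            io.read_annotation(annotation_path),
            io.read_design(design_path),
            target_type=target_type,
        )

    @property
    def ranks(self) -> pd.DataFrame:
        """The rank-normalized matrix (computed once, cached)."""
        if self._ranks is None:
            self._ranks = normalization.rank_normalize(self.matrix)
        return self._ranks

    def fit(
        self,
        alpha: float = 0.05,
        u: int | None = enrichment.DEFAULT_U,
        t: int | None = enrichment.DEFAULT_T,
        fdr_method: str = "auto",
        significance: float = enrichment.SIGNIFICANCE,
        exon_within_gene: bool = False,
    ) -> "DEMIResults":
        """Run the three-step pipeline and return the fitted results.

        ``alpha`` is the per-probe one-sided level; ``u`` the censoring
        limit on on-target probe counts (None disables); ``t`` the
        probe-multiplicity limit (None disables); ``fdr_method`` one of
        bh/by/auto.  With ``exon_within_gene`` the enrichment background
        is each exon's parent gene instead of the whole array.
        """
        if self.design.mode == "two_group":
            cls_ = probe_tests.classify_two_group(self.ranks, self.design, alpha)
        else:
            cls_ = probe_tests.classify_monotonic(self.ranks, self.design, alpha)
        ann = self._annotation_on_matrix()
        if exon_within_gene:
            table = enrichment.test_exons_within_gene(
                cls_, ann, u=u, t=t, fdr_method="bh" if fdr_method == "auto"
                else fdr_method, significance=significance,
            )
        else:
            table = enrichment.test_targets(
                cls_, ann, u=u, t=t, fdr_method=fdr_method,
                target_type=self.target_type, significance=significance,
            )
        return DEMIResults(self, cls_, table,
                           params=dict(alpha=alpha, u=u, t=t,
                                       fdr_method=table.attrs.get("fdr_method"),
                                       significance=significance))

    def _annotation_on_matrix(self) -> ProbeAnnotation:
        rec = self.annotation.records
        present = rec["probe_id"].isin(self.matrix.index)
        if not present.all():
            import warnings

            warnings.warn(
                f"dropping {(~present).sum()} annotation record(s) for probes "
                "absent from the matrix", stacklevel=3,
            )
            rec = rec[present]
        if rec.empty:
            raise ValidationError("annotation has no overlap with the matrix")
        return ProbeAnnotation(records=rec, alignments=self.annotation.alignments)


class DEMIResults:
    """Fitted target-level differential expression estimates.

    Attributes
    ----------
    table : DataFrame
        One row per (target, direction) with counts, censoring state,
        hypergeometric p and adjusted p (see ``io.RESULT_COLUMNS``).
    classification : ProbeClassification
        The per-probe up/down/none labels behind the table.
    """

    def __init__(self, model: DEMI, classification, table: pd.DataFrame,
                 params: dict):
        self.model = model
        self.classification = classification
        self.table = table
        self.params = params

    def significant(self, direction: str | None = None,
                    threshold: float | None = None) -> pd.DataFrame:
        """Targets with adjusted p below the significance threshold."""
        thr = self.params["significance"] if threshold is None else threshold
        return enrichment.significant_targets(self.table, direction, thr)

    def to_tsv(self, path) -> None:
        io.write_results(self.table, path)

    def summary(self) -> str:
        """Human-readable run summary, statsmodels-style."""
        cls_ = self.classification
        n_targets = self.table["target_id"].nunique()
        sig_up = len(self.significant("up"))
        sig_down = len(self.significant("down"))
        lines = [
            "Probe-level differential expression (hypergeometric enrichment)",
            "=" * 64,
            f"Design:               {self.model.design.mode}",
            f"Probe test:           {cls_.mode} (alpha={self.params['alpha']})",
            f"Probes (background n): {cls_.n}",
            f"  up  (|H|, X_up):    {cls_.x_up}",
            f"  down(|L|, X_down):  {cls_.x_down}",
            f"Targets tested:       {n_targets} ({self.table['target_type'].iloc[0]})",
            f"Censoring limit u:    {self.params['u']}",
            f"Multiplicity limit t: {self.params['t']}",
            f"FDR method:           {self.params['fdr_method']}",
            f"Significant (fdr<{self.params['significance']}): "
            f"{sig_up} up, {sig_down} down",
            "-" * 64,
        ]
        top = (
            self.table.sort_values(["fdr", "target_id"])
            .head(10)[io.RESULT_COLUMNS]
        )
        lines.append("Top targets:")
        lines.append(top.to_string(index=False,
                                   float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def plot_target(self, target_id: str, ax=None):
        """Plot per-sample relative ranks of one target's probes."""
        import matplotlib.pyplot as plt

        rec = self.model._annotation_on_matrix().records
        probes = rec.loc[rec["target_id"] == target_id, "probe_id"].unique()
        if len(probes) == 0:
            raise ValidationError(f"no probes annotated to {target_id!r}")
        ranks = self.model.ranks.loc[probes]
        if ax is None:
            _, ax = plt.subplots()
        design = self.model.design
        if design.mode == "two_group":
            order = list(design.test_samples) + list(design.ref_samples)
            xs = np.arange(len(order))
        else:
            order = list(design.covariate.sort_values().index)
            xs = design.covariate.loc[order].to_numpy()
        for _, row in ranks[order].iterrows():
            ax.plot(xs, row.to_numpy(), alpha=0.5, lw=0.8, color="steelblue")
        ax.set_xlabel("sample" if design.mode == "two_group" else "covariate")
        ax.set_ylabel("relative rank")
        ax.set_title(f"{target_id}: {len(probes)} probes")
        return ax
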