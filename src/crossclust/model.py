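"""Model/Results interface tying the whole analysis together.

``CrossOmicsCocluster`` is constructed from the raw tables (genus counts,
metabolite abundances, the 2x2 diet design, optional biomarkers) and owns
the preprocessing choices; ``fit`` runs prevalence filtering, the clr
transform, the cross-omic Spearman matrix, data-driven selection of the
number of biclusters and the spectral co-clustering itself, returning a
``CrossOmicsResults`` that carries the fitted partition, score traces and
per-sample bicluster summaries, and from which contrasts, biomarker
heatmaps, PCA ordinations, cross-validated classification and the two
figure archetypes are produced.

Example
-------
>>> from crossclust import simulate, CrossOmicsCocluster
>>> counts, mets, design, bio, truth = simulate.generate()
>>> res = CrossOmicsCocluster(counts, mets, design, biomarkers=bio).fit(seed=0)
>>> res.k, res.bicluster_model.row_labels.shape
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import associations, cocluster, correlation, preprocess, summaries, tables

logger = logging.getLogger(__name__)

__all__ = ["CrossOmicsCocluster", "CrossOmicsResults"]


class CrossOmicsCocluster:
    """Joint biclustering model for a paired genus/metabolite dataset.

    Parameters
    ----------
    counts, metabolites, design, biomarkers
        The input tables; samples are aligned (intersection, design
        order) at construction.
    filter_spec
        Detection/prevalence thresholds (defaults: 0.1% relative
        abundance at 10% prevalence for genera; > 0 at 10% for
        metabolites).
    pseudocount
        Constant added to filtered counts before the clr transform.
    shift
        How negative correlations are made nonnegative for the spectral
        step ('half' maps r to (r+1)/2; 'none' requires positive margins).
    """

    def __init__(
        self,
        counts: tables.CountTable,
        metabolites: tables.MetaboliteTable,
        design: tables.SampleDesign,
        biomarkers: tables.BiomarkerTable | None = None,
        filter_spec: preprocess.FilterSpec | None = None,
        pseudocount: float = 1.0,
        shift: str = "half",
    ) -> None:
        if biomarkers is not None:
            counts, metabolites, biomarkers, design = tables.align_samples(
                counts, metabolites, biomarkers, design=design
            )
        else:
            counts, metabolites, design = tables.align_samples(
                counts, metabolites, design=design
            )
        self.counts = counts
        self.metabolites = metabolites
        self.design = design
        self.biomarkers = biomarkers
        self.filter_spec = filter_spec or preprocess.FilterSpec()
        self.pseudocount = pseudocount
        self.shift = shift

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        metabolites: pd.DataFrame,
        design: pd.DataFrame,
        biomarkers: pd.DataFrame | None = None,
        taxonomy: dict[str, str] | None = None,
        **kwargs,
    ) -> "CrossOmicsCocluster":
        return cls(
            tables.CountTable(counts, taxonomy=taxonomy),
            tables.MetaboliteTable(metabolites),
            tables.SampleDesign(design),
            biomarkers=None if biomarkers is None else tables.BiomarkerTable(biomarkers),
            **kwargs,
        )

    def fit(
        self,
        k: int | None = None,
        k_grid=None,
        seed: int = 0,
        n_init: int = 10,
    ) -> "CrossOmicsResults":
        """Run the pipeline through the co-clustering stage.

        With ``k=None`` the number of biclusters is chosen by scanning
        ``k_grid`` (default 2..38, truncated to the matrix size) with
        Silhouette and Calinski-Harabasz scores on both axes.
        """
        genera_f, genus_report = preprocess.prevalence_filter(
            self.counts, self.filter_spec, "genera"
        )
        mets_f, met_report = preprocess.prevalence_filter(
            self.metabolites, self.filter_spec, "metabolites"
        )
        shifted, max_pp_shift = preprocess.add_pseudocount(genera_f, self.pseudocount)
        genus_clr = preprocess.clr_transform(shifted, pseudocount=self.pseudocount)
        corr = correlation.cross_correlation(mets_f, genus_clr)
        trace = None
        if k is None:
            trace = cocluster.select_k(
                corr, k_grid=k_grid, seed=seed, n_init=n_init, shift=self.shift
            )
            k = trace.chosen_k
        model = cocluster.fit_cocluster(
            corr, k=k, seed=seed, n_init=n_init, shift=self.shift
        )
        reordered, row_order, col_order, row_bounds, col_bounds = (
            cocluster.reorder_blockdiagonal(corr, model)
        )
        genus_rel = preprocess.relative_abundance(genera_f)
        summary = summaries.BiclusterSummary(
            metabolite_sums=summaries.sum_metabolites_by_bicluster(
                mets_f, model.row_labels, k=model.k
            ),
            genus_clr=summaries.sum_genera_by_bicluster(
                genus_rel, model.col_labels, k=model.k
            ),
        )
        return CrossOmicsResults(
            model=self,
            k=model.k,
            bicluster_model=model,
            selection_trace=trace,
            corr=corr,
            reordered=reordered,
            block_boundaries=(row_bounds, col_bounds),
            genus_report=genus_report,
            metabolite_report=met_report,
            genera_filtered=genera_f,
            metabolites_filtered=mets_f,
            genus_relabund=genus_rel,
            genus_clr=genus_clr,
            pseudocount_pp_shift=max_pp_shift,
            summary_tables=summary,
            seed=seed,
        )


@dataclass
class CrossOmicsResults:
    """Fitted bicluster partition plus everything derived from it."""

    model: CrossOmicsCocluster
    k: int
    bicluster_model: cocluster.BiclusterModel
    selection_trace: cocluster.SelectionTrace | None
    corr: correlation.CorrelationMatrix
    reordered: pd.DataFrame
    block_boundaries: tuple[list[int], list[int]]
    genus_report: preprocess.FilterReport
    metabolite_report: preprocess.FilterReport
    genera_filtered: tables.CountTable
    metabolites_filtered: tables.MetaboliteTable
    genus_relabund: pd.DataFrame
    genus_clr: preprocess.ClrMatrix
    pseudocount_pp_shift: float
    summary_tables: summaries.BiclusterSummary
    seed: int

    # -- derived analyses -------------------------------------------------

    def contrasts(
        self,
        pairs=summaries.DEFAULT_PAIRS,
        adjust: bool = False,
    ) -> pd.DataFrame:
        """Feature-level group contrasts in the published table layout.

        Genera are contrasted on the relative-abundance scale and
        metabolites on the raw scale; rows carry bicluster membership.
        """
        m = self.bicluster_model
        genus_map = {f: int(l) for f, l in zip(m.col_ids, m.col_labels)}
        met_map = {f: int(l) for f, l in zip(m.row_ids, m.row_labels)}
        genus_tab = summaries.contrast_table(
            self.genus_relabund, self.model.design, pairs, bicluster_of=genus_map,
            adjust=adjust,
        )
        genus_tab.insert(0, "axis", "genus")
        met_tab = summaries.contrast_table(
            self.metabolites_filtered.data, self.model.design, pairs,
            bicluster_of=met_map, adjust=adjust,
        )
        met_tab.insert(0, "axis", "metabolite")
        return pd.concat([genus_tab, met_tab], ignore_index=True)

    def bicluster_contrasts(self, pairs=summaries.DEFAULT_PAIRS) -> pd.DataFrame:
        """Group contrasts of the per-bicluster summed abundances."""
        met = summaries.contrast_table(
            self.summary_tables.metabolite_sums, self.model.design, pairs
        )
        met.insert(0, "axis", "metabolite_sum")
        gen = summaries.contrast_table(
            self.summary_tables.genus_clr, self.model.design, pairs
        )
        gen.insert(0, "axis", "genus_clr_sum")
        return pd.concat([met, gen], ignore_index=True)

    def biomarker_heatmaps(self) -> dict[str, associations.AssociationHeatmap]:
        """Spearman heatmaps of biomarkers vs bicluster summaries."""
        if self.model.biomarkers is None:
            raise tables.ValidationError("no biomarker table was supplied")
        return {
            "metabolites": associations.biomarker_associations(
                self.summary_tables.metabolite_sums, self.model.biomarkers
            ),
            "genera": associations.biomarker_associations(
                self.summary_tables.genus_clr, self.model.biomarkers
            ),
        }

    def pca(self, what: str = "summaries", **kwargs) -> associations.PcaResult:
        """PCA ordination of bicluster summaries or of all features."""
        if what == "summaries":
            X = pd.concat(
                [
                    self.summary_tables.metabolite_sums.add_prefix("met_"),
                    self.summary_tables.genus_clr.add_prefix("gen_"),
                ],
                axis=1,
            )
        elif what == "features":
            X = pd.concat(
                [self.metabolites_filtered.data, self.genus_clr.data], axis=1
            )
        else:
            raise ValueError("what must be 'summaries' or 'features'")
        return associations.pca(X, design=self.model.design, **kwargs)

    def classify(
        self,
        task: str = "overall_diet",
        scope: str = "all",
        bicluster: int | None = None,
        classifier=None,
        folds: int = 5,
        seed: int | None = None,
    ) -> associations.CvReport:
        """Cross-validated classification of a diet factor.

        Features are raw metabolites plus clr genera; ``scope``
        'bicluster' restricts to the members of ``bicluster``.
        """
        feats = pd.concat(
            [self.metabolites_filtered.data, self.genus_clr.data], axis=1
        )
        scope_name = scope
        if scope == "bicluster":
            if bicluster is None:
                raise ValueError("scope='bicluster' needs a bicluster index")
            m = self.bicluster_model
            keep = m.row_members(bicluster) + m.col_members(bicluster)
            feats = feats[keep]
            scope_name = f"bicluster_{bicluster}"
        elif scope != "all":
            raise ValueError("scope must be 'all' or 'bicluster'")
        return associations.cv_classification(
            feats,
            self.model.design,
            task=task,
            feature_scope=scope_name,
            classifier=classifier,
            folds=folds,
            seed=self.seed if seed is None else seed,
        )

    # -- plotting ---------------------------------------------------------

    def plot_heatmap(self, path=None, ax=None):
        from . import plots

        return plots.plot_cocluster_heatmap(
            self.reordered, self.block_boundaries, path=path, ax=ax
        )

    def plot_panels(self, axis: str = "metabolites", biomarker: str | None = None, path=None):
        from . import plots

        summary = (
            self.summary_tables.metabolite_sums
            if axis == "metabolites"
            else self.summary_tables.genus_clr
        )
        bio = None
        if biomarker is not None:
            if self.model.biomarkers is None:
                raise tables.ValidationError("no biomarker table was supplied")
            if biomarker not in self.model.biomarkers.data.columns:
                raise tables.ValidationError(f"unknown biomarker {biomarker!r}")
            bio = self.model.biomarkers.data[biomarker]
        return plots.plot_bicluster_panels(summary, self.model.design, biomarker=bio, path=path)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        m = self.bicluster_model
        lines = [
            "Cross-omic spectral co-clustering",
            "=" * 46,
            f"samples                  {len(self.model.design.sample_ids):>6}",
            f"genera in / kept         {self.genus_report.n_features_in:>6} / {self.genus_report.n_features_kept}",
            f"metabolites in / kept    {self.metabolite_report.n_features_in:>6} / {self.metabolite_report.n_features_kept}",
            f"mean data loss (genera)  {self.genus_report.mean_data_loss * 100:>8.3f} %",
            f"pseudocount max shift    {self.pseudocount_pp_shift:>8.4f} pp",
            f"biclusters (k)           {self.k:>6}"
            + ("  (data-driven)" if self.selection_trace is not None else "  (fixed)"),
            f"shift mode               {m.shift:>6}",
            f"seed                     {m.seed:>6}",
            "-" * 46,
            "bicluster   metabolites   genera",
        ]
        for b in range(self.k):
            lines.append(
                f"{b:>9}   {int((m.row_labels == b).sum()):>11}   {int((m.col_labels == b).sum()):>6}"
            )
        if self.selection_trace is not None:
            sc = self.selection_trace.scores.loc[self.k]
            lines += [
                "-" * 46,
                f"silhouette (met / gen)   {sc['silhouette_metabolites']:.3f} / {sc['silhouette_genera']:.3f}",
                f"Calinski-H (met / gen)   {sc['calinski_metabolites']:.1f} / {sc['calinski_genera']:.1f}",
            ]
        return "\n".join(lines)
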