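"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes filter -> pseudocount/clr -> cross-correlation
-> (select_k | fixed k) -> co-clustering -> reorder -> summaries ->
contrasts -> biomarker associations -> PCA -> optional CV, writing every
stage's output as text and a manifest recording the configuration and the
data-driven decisions taken, so that a rerun with the same configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import CrossOmicsCocluster
from .preprocess import FilterSpec
from .tables import (
    BiomarkerTable,
    read_design,
    read_table,
    read_taxonomy,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Paths and knobs for a full pipeline run."""

    counts: str
    metabolites: str
    design: str
    biomarkers: str | None = None
    taxonomy: str | None = None
    orientation: str = "samples_as_rows"
    detection: float = 0.001
    prevalence: float = 0.10
    metabolite_detection: float = 0.0
    pseudocount: float = 1.0
    shift: str = "half"
    k: int | None = None
    k_grid: list[int] | None = None
    seed: int = 0
    n_init: int = 10
    contrast_pairs: list[list[str]] = field(
        default_factory=lambda: [["HFD", "HFD+XOS"], ["HFD", "LFD"]]
    )
    run_cv: bool = False
    cv_task: str = "fat"
    out: str = "crossclust_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _write_csv(df: pd.DataFrame, path: Path, index_label="id") -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts + manifest under ``config.out``."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "decisions": {},
        "stages": [],
    }

    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
    counts = read_table(config.counts, config.orientation, kind="counts")
    if taxonomy:
        counts.taxonomy = taxonomy
    metabolites = read_table(config.metabolites, config.orientation, kind="metabolites")
    design = read_design(config.design)
    biomarkers = None
    if config.biomarkers:
        p = Path(config.biomarkers)
        if p.exists():
            biomarkers = read_table(p, config.orientation, kind="biomarkers")
        else:
            logger.warning("biomarker file %s missing; association stages skipped", p)

    model = CrossOmicsCocluster(
        counts,
        metabolites,
        design,
        biomarkers=biomarkers,
        filter_spec=FilterSpec(
            detection=config.detection,
            prevalence=config.prevalence,
            metabolite_detection=config.metabolite_detection,
        ),
        pseudocount=config.pseudocount,
        shift=config.shift,
    )
    res = model.fit(
        k=config.k,
        k_grid=config.k_grid or range(2, 39),
        seed=config.seed,
        n_init=config.n_init,
    )
    manifest["decisions"]["k"] = "fixed" if config.k is not None else "data-driven"
    manifest["decisions"]["chosen_k"] = res.k
    manifest["decisions"]["shift"] = config.shift
    manifest["decisions"]["pseudocount_max_pp_shift"] = res.pseudocount_pp_shift

    def stage(name: str, path: Path) -> None:
        manifest["stages"].append({"name": name, "path": path.name})

    (out / "genus_filter_report.json").write_text(res.genus_report.to_json())
    stage("genus_filter_report", out / "genus_filter_report.json")
    (out / "metabolite_filter_report.json").write_text(res.metabolite_report.to_json())
    stage("metabolite_filter_report", out / "metabolite_filter_report.json")
    _write_csv(res.genera_filtered.data, out / "genera_filtered.csv", "sample_id")
    stage("genera_filtered", out / "genera_filtered.csv")
    _write_csv(res.metabolites_filtered.data, out / "metabolites_filtered.csv", "sample_id")
    stage("metabolites_filtered", out / "metabolites_filtered.csv")
    _write_csv(res.genus_clr.data, out / "genus_clr.csv", "sample_id")
    stage("genus_clr", out / "genus_clr.csv")
    _write_csv(res.corr.rho, out / "correlation.csv", "metabolite")
    stage("correlation", out / "correlation.csv")
    if res.selection_trace is not None:
        _write_csv(res.selection_trace.scores, out / "selection_trace.csv", "k")
        stage("selection_trace", out / "selection_trace.csv")
    (out / "bicluster_model.json").write_text(
        json.dumps(res.bicluster_model.to_dict(), indent=2)
    )
    stage("bicluster_model", out / "bicluster_model.json")
    _write_csv(res.reordered, out / "correlation_blockordered.csv", "metabolite")
    stage("correlation_blockordered", out / "correlation_blockordered.csv")
    summary = pd.concat(
        [
            res.summary_tables.metabolite_sums.add_prefix("met_"),
            res.summary_tables.genus_clr.add_prefix("gen_"),
            res.model.design.frame,
        ],
        axis=1,
    )
    _write_csv(summary, out / "bicluster_summaries.csv", "sample_id")
    stage("bicluster_summaries", out / "bicluster_summaries.csv")
    pairs = [tuple(p) for p in config.contrast_pairs]
    contrasts = res.contrasts(pairs=pairs)
    contrasts.to_csv(out / "contrasts.csv", index=False, float_format=_FLOAT_FMT)
    stage("contrasts", out / "contrasts.csv")

    if biomarkers is not None:
        heatmaps = res.biomarker_heatmaps()
        for axis, hm in heatmaps.items():
            ordered = hm.ordered()
            _write_csv(ordered.rho, out / f"biomarker_rho_{axis}.csv", "biomarker")
            _write_csv(ordered.p, out / f"biomarker_p_{axis}.csv", "biomarker")
            ordered.stars.to_csv(out / f"biomarker_stars_{axis}.csv", index_label="biomarker")
            stage(f"biomarker_heatmap_{axis}", out / f"biomarker_rho_{axis}.csv")
    pca_res = res.pca("summaries")
    _write_csv(pca_res.scores, out / "pca_scores.csv", "sample_id")
    _write_csv(pca_res.loadings, out / "pca_loadings.csv", "feature")
    (out / "pca_meta.json").write_text(
        json.dumps(
            {
                "explained_variance_ratio": [
                    float(v) for v in pca_res.explained_variance_ratio
                ],
                "ellipses": pca_res.ellipses,
            },
            indent=2,
        )
    )
    stage("pca", out / "pca_scores.csv")
    if config.run_cv:
        report = res.classify(task=config.cv_task, seed=config.seed)
        (out / "cv_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        stage("cv", out / "cv_report.json")

    res.plot_heatmap(path=out / "heatmap.png")
    stage("heatmap", out / "heatmap.png")
    res.plot_panels(axis="metabolites", path=out / "bicluster_panels.png")
    stage("bicluster_panels", out / "bicluster_panels.png")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stage outputs in %s", len(manifest["stages"]), out)
    return out
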