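"""End-to-end orchestration of the four diseaseome-construction stages.

``build_diseaseome`` is the in-memory driver: preprocessing → gene z-scores
→ pathway dissection → M-scoring → redundancy reduction → DRG selection
(with optional parameter optimization on a random-gene-set background) →
two-round consensus clustering. ``run_pipeline`` wraps it with file I/O: it
reads a :class:`PipelineConfig`, writes every intermediate artifact (GMT of
split and reduced sets, audit and optimization tables, M-score matrices, the
model JSON) and a run log with set counts at each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as dio
from .clustering import (
    ClusteringParams,
    assignments_table,
    combine_scores,
    two_round_clustering,
)
from .granularity import SplitParams, dissect_collection, split_map
from .preprocess import PreprocessParams, preprocess
from .redundancy import RedundancyParams, jaccard_reduce, set_packing_reduce
from .scoring import gene_zscores, mscores
from .selection import (
    FilterParams,
    OptimizationReport,
    filter_gene_sets,
    optimize_parameters,
    sample_random_genesets,
    significance_proportions,
)
from .types import (
    DiseaseomeModel,
    ExpressionDataset,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-level pipeline configuration (see ``from_yaml``)."""

    datasets: list[dict]  # each: {expression, groups, id}
    collections: list[dict]  # each: {path, source}
    outdir: str = "diseaseome_out"
    seed: int = 0
    optimize: bool = False
    preprocess_params: PreprocessParams = field(default_factory=PreprocessParams)
    split_params: SplitParams = field(default_factory=SplitParams)
    redundancy_params: RedundancyParams = field(default_factory=RedundancyParams)
    filter_params: FilterParams = field(default_factory=FilterParams)
    clustering_params: ClusteringParams = field(default_factory=ClusteringParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not doc.get("datasets"):
            raise ValueError("config needs at least one dataset")
        if not doc.get("collections"):
            raise ValueError("config needs at least one gene-set collection")
        for spec in doc["datasets"]:
            for key in ("expression", "groups"):
                if not Path(spec[key]).exists():
                    raise FileNotFoundError(spec[key])
        for spec in doc["collections"]:
            if not Path(spec["path"]).exists():
                raise FileNotFoundError(spec["path"])

        def params(cls_, key):
            return cls_(**doc.get(key, {}))

        filt = doc.get("filter", {})
        optimize = filt == "optimize" or doc.get("optimize", False)
        return cls(
            datasets=doc["datasets"],
            collections=doc["collections"],
            outdir=doc.get("outdir", "diseaseome_out"),
            seed=int(doc.get("seed", 0)),
            optimize=optimize,
            preprocess_params=params(PreprocessParams, "preprocess"),
            split_params=params(SplitParams, "split"),
            redundancy_params=params(RedundancyParams, "redundancy"),
            filter_params=FilterParams(**filt) if isinstance(filt, dict) and filt else FilterParams(),
            clustering_params=params(ClusteringParams, "clustering"),
        )


@dataclass
class PipelineResult:
    model: DiseaseomeModel
    stage_counts: dict[str, int]
    optimization: Optional[OptimizationReport] = None


def build_diseaseome(
    datasets: Sequence[ExpressionDataset],
    collection: GeneSetCollection,
    preprocess_params: PreprocessParams = PreprocessParams(),
    split_params: SplitParams = SplitParams(),
    redundancy_params: RedundancyParams = RedundancyParams(),
    filter_params: Optional[FilterParams] = FilterParams(),
    clustering_params: ClusteringParams = ClusteringParams(),
    seed: int = 0,
    n_random_sets: int = 1000,
    outdir: Optional[Path] = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``filter_params=None`` triggers parameter optimization on a random
    background of ``n_random_sets`` sets. When the requested ``min_datasets``
    exceeds the number of cohorts it is clamped (with a warning) so the
    pipeline stays operable from a single dataset.
    """
    counts: dict[str, int] = {"input_sets": len(collection)}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    clean = [preprocess(d, preprocess_params) for d in datasets]
    zmats = [gene_zscores(d) for d in clean]
    logger.info("stage preprocess: %d datasets", len(clean))

    split = dissect_collection(collection, zmats, split_params, seed=seed)
    counts["split_sets"] = len(split)
    logger.info("stage granularity: %d -> %d sets", len(collection), len(split))
    if outdir is not None:
        dio.write_gmt(split, outdir / "01_split.gmt")
        split_map(split).to_csv(outdir / "01_split_map.tsv", sep="\t", index=False)

    ms = [mscores(split, z) for z in zmats]
    if outdir is not None:
        for m in ms:
            dio.write_mscores(m, outdir / f"02_mscores_{m.dataset_id}.tsv")

    packed, audit1 = set_packing_reduce(split, ms, redundancy_params)
    reduced, audit2 = jaccard_reduce(packed, redundancy_params)
    counts["after_set_packing"] = len(packed)
    counts["after_jaccard"] = len(reduced)
    logger.info(
        "stage redundancy: %d -> %d (packing) -> %d (jaccard)",
        len(split),
        len(packed),
        len(reduced),
    )
    if outdir is not None:
        dio.write_gmt(reduced, outdir / "03_reduced.gmt")
        pd.DataFrame([vars(r) for r in audit1 + audit2]).to_csv(
            outdir / "03_removals.tsv", sep="\t", index=False
        )

    ms_red = [m.subset(reduced.ids) for m in ms]
    props = significance_proportions(reduced, ms_red)
    report = None
    if filter_params is None:
        random_sets = sample_random_genesets(
            reduced.gene_universe, reduced, n=n_random_sets, seed=seed
        )
        ms_rand = [mscores(random_sets, z) for z in zmats]
        report = optimize_parameters(reduced, ms_red, random_sets, ms_rand)
        filter_params = FilterParams(
            perc_samples=report.chosen.perc_samples,
            min_datasets=report.chosen.min_datasets,
        )
        logger.info(
            "stage selection: optimized parameters perc_samples=%s min_datasets=%s",
            filter_params.perc_samples,
            filter_params.min_datasets,
        )
        if outdir is not None:
            report.to_frame().to_csv(
                outdir / "04_optimization_grid.tsv", sep="\t", index=False
            )
    if filter_params.min_datasets > len(datasets):
        logger.warning(
            "min_datasets=%d exceeds the %d available datasets; clamping",
            filter_params.min_datasets,
            len(datasets),
        )
        filter_params = dataclasses.replace(
            filter_params, min_datasets=len(datasets)
        )

    drgs = filter_gene_sets(reduced, props, filter_params)
    counts["drgs"] = len(drgs)
    counts["drg_genes"] = len(drgs.gene_universe)
    logger.info("stage selection: %d DRGs (%d genes)", len(drgs), counts["drg_genes"])
    if outdir is not None:
        dio.write_gmt(drgs, outdir / "05_drgs.gmt")

    provenance = {
        "seed": seed,
        "datasets": [d.dataset_id for d in datasets],
        "preprocess": vars(preprocess_params),
        "split": vars(split_params),
        "redundancy": vars(redundancy_params),
        "filter": vars(filter_params),
        "counts": counts,
    }
    if len(drgs) == 0:
        model = DiseaseomeModel(drgs=drgs, provenance=provenance)
    else:
        matrix = combine_scores([m.subset(drgs.ids) for m in ms_red], drgs)
        model = two_round_clustering(
            matrix, drgs, clustering_params, provenance=provenance
        )
    counts["round1_clusters"] = len(model.cluster_tree)
    counts["round2_clusters"] = sum(len(v) for v in model.cluster_tree.values())
    model.provenance["counts"] = counts

    if outdir is not None:
        dio.save_model(model, outdir / "06_model.json")
        assignments_table(model).to_csv(
            outdir / "06_clusters.tsv", sep="\t", index=False
        )
        with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
            json.dump({"counts": counts, "provenance": model.provenance}, fh, indent=1)
            fh.write("\n")
    return PipelineResult(model=model, stage_counts=counts, optimization=report)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point mirroring the end-to-end run script."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("diseaseome")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        datasets = [
            dio.read_expression(d["expression"], d["groups"], d["id"])
            for d in config.datasets
        ]
        merged: list = []
        for spec in config.collections:
            merged.extend(dio.read_gmt(spec["path"], spec["source"]))
        collection = GeneSetCollection(merged)
        return build_diseaseome(
            datasets,
            collection,
            preprocess_params=config.preprocess_params,
            split_params=config.split_params,
            redundancy_params=config.redundancy_params,
            filter_params=None if config.optimize else config.filter_params,
            clustering_params=config.clustering_params,
            seed=config.seed,
            outdir=outdir,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
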