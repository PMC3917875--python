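"""End-to-end pipeline: preprocess -> bimodality -> clusters -> metagenes ->
consensus modules -> SigClust, with every stage's seed derived from one
top-level seed so a rerun is bit-identical."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .bimodality import select_bimodal_genes
from .clustering import cluster_bimodal_genes
from .consensus import (
    ConsensusParams,
    build_modules,
    cluster_score_correlations,
    define_modules,
    filter_recurrent_clusters,
    score_modules,
)
from .metagene import compute_metagene, score_compendium
from .preprocess import preprocess_compendium
from .sigclust import pairwise_module_sigclust

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fdr_threshold: float = 0.05
    null_draws: int = 10_000
    k_max: int = 20
    min_cluster_size: int = 3
    r_threshold: float = 0.7
    min_neighbors: int = 6
    membership_fraction: float = 1.0 / 3.0
    n_modules: int | str = "auto"
    sigclust_sims: int = 1000
    seed: int = 0
    # optional fixed seed for the null BI distribution, so runs on same-size
    # datasets can share one cached null; None derives it from `seed`
    null_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0,1)")
        if self.null_draws < 100 or self.k_max < 1 or self.min_cluster_size < 2:
            raise ValueError("invalid pipeline parameters")
        ConsensusParams(
            r_threshold=self.r_threshold,
            min_neighbors=self.min_neighbors,
            membership_fraction=self.membership_fraction,
            n_modules=self.n_modules,
        )

    def consensus_params(self) -> ConsensusParams:
        return ConsensusParams(
            r_threshold=self.r_threshold,
            min_neighbors=self.min_neighbors,
            membership_fraction=self.membership_fraction,
            n_modules=self.n_modules,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    compendium: object
    bimodal: dict
    clusters: list
    score_matrix: object
    corr: np.ndarray
    retained_ids: list[str]
    assignment: dict
    modules: list
    sigclust: dict
    module_scores: dict


def run_pipeline(
    datasets,
    config: PipelineConfig | None = None,
    outdir=None,
    run_sigclust: bool = True,
    null_cache: dict | None = None,
) -> PipelineResult:
    """Run discovery end to end on a list of (raw) ExpressionDatasets.

    ``null_cache`` may carry pre-built null BI distributions keyed by
    (n_samples, null_draws, seed); the pipeline fills it as it goes.
    """
    from .preprocess import restrict_to_common_genes

    config = config or PipelineConfig()
    seed = config.seed
    if null_cache is None:
        null_cache = {}

    logger.info("stage preprocess: %d datasets", len(datasets))
    comp = preprocess_compendium(restrict_to_common_genes(list(datasets)))

    bimodal = {}
    bimodal_seed = (
        derive_seed(seed, "bimodality") if config.null_seed is None else config.null_seed
    )
    for ds in comp.datasets:
        recs = select_bimodal_genes(
            ds,
            fdr_threshold=config.fdr_threshold,
            n_draws=config.null_draws,
            seed=bimodal_seed,
            null_cache=null_cache,
        )
        bimodal[ds.dataset_id] = recs
        logger.info(
            "stage bimodality: %s: %d/%d significant",
            ds.dataset_id, sum(r.significant for r in recs), len(recs),
        )

    clusters = []
    for ds in comp.datasets:
        sig = [r.gene_id for r in bimodal[ds.dataset_id] if r.significant]
        cls = cluster_bimodal_genes(
            ds, sig,
            k_max=config.k_max,
            min_cluster_size=config.min_cluster_size,
            seed=derive_seed(seed, "clustering"),
        )
        for cl in cls:
            compute_metagene(cl, ds)
        clusters.extend(cls)
    logger.info("stage clusters: %d clusters across datasets", len(clusters))
    if len(clusters) < 2:
        raise RuntimeError("stage clusters: fewer than 2 clusters discovered; cannot continue")

    score_matrix = score_compendium(clusters, comp)
    corr = cluster_score_correlations(score_matrix)
    params = config.consensus_params()
    retained_ids = filter_recurrent_clusters(corr, params, score_matrix.cluster_ids)
    logger.info("stage consensus: %d/%d clusters recurrent", len(retained_ids), len(clusters))
    if len(retained_ids) < 2:
        raise RuntimeError("stage consensus: fewer than 2 recurrent clusters")
    ridx = [score_matrix.cluster_ids.index(c) for c in retained_ids]
    corr_sub = corr[np.ix_(ridx, ridx)]
    assignment = define_modules(corr_sub, params, retained_ids)
    modules = build_modules(assignment, clusters, comp, params)
    logger.info("stage consensus: %d modules", len(modules))

    sig_results = {}
    if run_sigclust:
        for method in ("hard", "soft"):
            sig_results[method] = pairwise_module_sigclust(
                assignment, corr_sub, retained_ids,
                method=method,
                n_sims=config.sigclust_sims,
                seed=derive_seed(seed, "sigclust"),
            )

    module_scores = {ds.dataset_id: score_modules(modules, ds) for ds in comp.datasets}

    result = PipelineResult(
        compendium=comp,
        bimodal=bimodal,
        clusters=clusters,
        score_matrix=score_matrix,
        corr=corr,
        retained_ids=retained_ids,
        assignment=assignment,
        modules=modules,
        sigclust=sig_results,
        module_scores=module_scores,
    )
    if outdir is not None:
        write_results(result, config, Path(outdir))
    return result


def write_results(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    from .io import write_gmt, write_scores_tsv, write_weights_tsv

    outdir.mkdir(parents=True, exist_ok=True)
    for ds_id, recs in result.bimodal.items():
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id, "bi": r.bi, "p_emp": r.p_emp,
                    "q": r.q, "significant": int(r.significant),
                }
                for r in recs
            ]
        ).to_csv(outdir / f"bimodality_{ds_id}.tsv", sep="\t", index=False, float_format="%.10g")

    pd.DataFrame(
        [
            {"cluster_id": cl.cluster_id, "dataset_id": cl.source_dataset_id, "gene_id": g}
            for cl in result.clusters
            for g in cl.gene_ids
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_gmt({cl.cluster_id: cl.gene_ids for cl in result.clusters}, outdir / "clusters.gmt")
    write_scores_tsv(result.score_matrix, outdir / "cluster_scores.tsv")

    pd.DataFrame(
        sorted(result.assignment.items()), columns=["cluster_id", "module_id"]
    ).to_csv(outdir / "module_assignment.tsv", sep="\t", index=False)
    write_gmt({m.module_id: m.gene_ids for m in result.modules}, outdir / "modules.gmt")
    write_weights_tsv(result.modules, outdir / "module_weights.tsv")

    for method, results in result.sigclust.items():
        pd.DataFrame(
            [
                {
                    "module_a": r.pair[0], "module_b": r.pair[1],
                    "ci": r.ci_observed, "p": r.p_value, "sigma_n2": r.sigma_n2,
                }
                for r in results
            ]
        ).to_csv(outdir / f"sigclust_{method}.tsv", sep="\t", index=False, float_format="%.10g")

    for ds_id, ms in result.module_scores.items():
        write_scores_tsv(ms, outdir / f"module_scores_{ds_id}.tsv")

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_modules": len(result.modules),
        "versions": {
            "coexmod": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
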