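"""Consensus modules from recurrent cross-dataset cluster patterns.

Cluster score rows are correlated across the whole compendium; clusters
highly correlated (r above a threshold, default 0.7) with at least a minimum
number of other clusters (default 6) are retained as recurrent patterns.
Rows of the retained correlation submatrix are then hierarchically clustered
(Euclidean distance, complete linkage) and the tree is cut into modules —
either a fixed number or, by default, the cut maximizing the mean silhouette.
Each module's gene set keeps the genes present in more than a third of its
member clusters, and its weight vector is the PC1 of that gene set over the
pooled samples of the contributing datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.metrics import silhouette_score

from .metagene import ClusterScoreMatrix, pc1_weights

logger = logging.getLogger(__name__)


@dataclass
class ConsensusParams:
    r_threshold: float = 0.7
    min_neighbors: int = 6
    membership_fraction: float = 1.0 / 3.0  # strict "more than a third"
    linkage: str = "complete"
    distance: str = "euclidean"
    n_modules: int | str = "auto"

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (0,1)")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if not (0.0 < self.membership_fraction < 1.0):
            raise ValueError("membership_fraction must be in (0,1)")
        if self.linkage != "complete" or self.distance != "euclidean":
            raise ValueError("only complete linkage with euclidean distance is supported")


@dataclass
class Module:
    module_id: str
    member_cluster_ids: list[str]
    gene_ids: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None
    contributing_samples: set[tuple[str, str]] = field(default_factory=set)
    contributing_datasets: list[str] = field(default_factory=list)


@dataclass
class ModuleScores:
    module_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.module_ids), len(self.sample_ids)):
            raise ValueError("score matrix shape does not match id lists")


def cluster_score_correlations(m: ClusterScoreMatrix) -> np.ndarray:
    """Pairwise Pearson correlation between cluster score rows."""
    if len(m.cluster_ids) < 2:
        raise ValueError("need at least 2 clusters")
    sds = m.scores.std(axis=1)
    bad = [cid for cid, sd in zip(m.cluster_ids, sds) if sd == 0]
    if bad:
        raise ValueError(f"zero-variance score rows for clusters: {bad}")
    corr = np.corrcoef(m.scores)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def filter_recurrent_clusters(
    corr: np.ndarray, params: ConsensusParams, cluster_ids: list[str] | None = None
) -> list[int] | list[str]:
    """Keep clusters correlated at r > threshold (strict) with >= min_neighbors others.

    Returns retained indices, or retained ids when ``cluster_ids`` is given.
    """
    corr = np.asarray(corr, dtype=float)
    off = corr.copy()
    np.fill_diagonal(off, -np.inf)
    degree = (off > params.r_threshold).sum(axis=1)
    kept = np.flatnonzero(degree >= params.min_neighbors)
    if cluster_ids is not None:
        return [cluster_ids[i] for i in kept]
    return list(kept)


def define_modules(
    corr_sub: np.ndarray, params: ConsensusParams, cluster_ids: list[str] | None = None
) -> dict:
    """Assign retained clusters to modules by hierarchical clustering.

    Feature vectors are the rows of the correlation submatrix.  With
    ``n_modules='auto'`` the cut k in 2..min(15, n-1) maximizing the mean
    silhouette is chosen; a degenerate silhouette falls back to k=2.
    Module ids ``mod1, mod2, ...`` are ordered by member count descending.
    """
    corr_sub = np.asarray(corr_sub, dtype=float)
    n = corr_sub.shape[0]
    if n < 2:
        raise ValueError("need at least 2 retained clusters")
    if cluster_ids is None:
        cluster_ids = [str(i) for i in range(n)]
    Z = linkage(corr_sub, method=params.linkage, metric=params.distance)

    if params.n_modules == "auto":
        best_k, best_sil = None, -np.inf
        for k in range(2, min(15, n - 1) + 1):
            labels = cut_tree(Z, n_clusters=k)[:, 0]
            if len(np.unique(labels)) < 2:
                continue
            try:
                sil = silhouette_score(corr_sub, labels, metric=params.distance)
            except ValueError:
                continue
            if sil > best_sil + 1e-12:
                best_k, best_sil = k, sil
        if best_k is None or not np.isfinite(best_sil) or best_sil <= -1 + 1e-12:
            logger.warning("silhouette degenerate; falling back to k=2")
            best_k = 2
        k = best_k
        logger.info("auto cut selected k=%d (mean silhouette %.3f)", k, best_sil)
    else:
        k = int(params.n_modules)
        if not (1 <= k <= n):
            raise ValueError(f"n_modules={k} out of range for {n} clusters")
    labels = cut_tree(Z, n_clusters=k)[:, 0]

    # order module ids by size descending (ties by first-seen label)
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    ordered = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    rename = {lab: f"mod{i + 1}" for i, lab in enumerate(ordered)}
    return {cid: rename[lab] for cid, lab in zip(cluster_ids, labels)}


def module_gene_sets(
    assignment: dict, clusters: list, params: ConsensusParams
) -> dict[str, list[str]]:
    """Distill each module to the genes in more than ``membership_fraction`` of
    its member clusters (strict inequality, so 1-of-3 is excluded)."""
    by_id = {cl.cluster_id: cl for cl in clusters}
    modules: dict[str, list[str]] = {}
    for mod in sorted(set(assignment.values())):
        members = [by_id[cid] for cid, m in assignment.items() if m == mod]
        counts: dict[str, int] = {}
        for cl in members:
            for g in cl.gene_ids:
                counts[g] = counts.get(g, 0) + 1
        cutoff = params.membership_fraction * len(members)
        genes = sorted(g for g, c in counts.items() if c > cutoff)
        if not genes:
            top = sorted(counts.items(), key=lambda kv: -kv[1])[:10]
            raise ValueError(
                f"module {mod}: empty gene set after membership rule; "
                f"top gene frequencies: {top}"
            )
        modules[mod] = genes
    return modules


def build_modules(
    assignment: dict, clusters: list, comp, params: ConsensusParams
) -> list[Module]:
    """Assemble Module objects: member clusters, distilled genes, PC1 weights."""
    gene_sets = module_gene_sets(assignment, clusters, params)
    by_id = {cl.cluster_id: cl for cl in clusters}
    out = []
    for mod in sorted(gene_sets, key=lambda m: int(m.replace("mod", ""))):
        member_ids = sorted(cid for cid, m in assignment.items() if m == mod)
        contributing = sorted({by_id[cid].source_dataset_id for cid in member_ids})
        module = Module(
            module_id=mod,
            member_cluster_ids=member_ids,
            gene_ids=gene_sets[mod],
            contributing_datasets=contributing,
            contributing_samples={
                (d, s) for d in contributing for s in comp.get(d).sample_ids
            },
        )
        module_weights(module, comp)
        out.append(module)
    return out


def module_weights(module: Module, comp) -> Module:
    """PC1 weights of the module gene set over the pooled contributing samples.

    The pooled matrix concatenates each contributing dataset's z-scored
    submatrix; with fewer than two genes, the single gene gets weight 1.
    """
    missing = [g for g in module.gene_ids if g not in set(comp.gene_universe)]
    if missing:
        raise ValueError(f"{module.module_id}: genes missing from universe: {missing[:5]}")
    if len(module.gene_ids) < 2:
        logger.warning("%s: single-gene module; weight set to 1", module.module_id)
        module.weights = np.array([1.0])
        return module
    datasets = module.contributing_datasets or [ds.dataset_id for ds in comp.datasets]
    blocks = [
        comp.get(d).values[comp.get(d).gene_index(module.gene_ids)] for d in datasets
    ]
    module.weights = pc1_weights(np.hstack(blocks))
    return module


def score_module(module: Module, ds, return_retained: bool = False):
    """Project a dataset's samples onto a module weight vector.

    Identical projection contract to cluster metagene scoring: only genes
    present in the dataset contribute, and the retained fraction of the
    weight-vector norm is reported.  Cross-platform inputs are expected to be
    median-collapsed by gene symbol and z-scored before scoring.
    """
    if module.weights is None:
        raise ValueError(f"{module.module_id}: weights not computed")
    present = [i for i, g in enumerate(module.gene_ids) if g in set(ds.gene_ids)]
    if not present:
        raise ValueError(f"{module.module_id}: no module gene present in {ds.dataset_id}")
    w = module.weights[present]
    retained = float(np.linalg.norm(w))
    if retained < 0.5:
        logger.warning(
            "%s on %s: only %.2f of weight norm retained",
            module.module_id, ds.dataset_id, retained,
        )
    genes = [module.gene_ids[i] for i in present]
    scores = w @ ds.values[ds.gene_index(genes)]
    if return_retained:
        return scores, retained
    return scores


def score_modules(modules: list[Module], ds) -> ModuleScores:
    return ModuleScores(
        module_ids=[m.module_id for m in modules],
        sample_ids=list(ds.sample_ids),
        scores=np.vstack([score_module(m, ds) for m in modules]),
    )
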