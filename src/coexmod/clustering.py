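"""Within-dataset organization of bimodal genes into co-expression clusters.

Genes are treated as observations with their standardized across-sample
profiles as features and partitioned by Gaussian-mixture model-based
clustering.  The number of clusters and the covariance family (spherical or
diagonal, with shared- or per-component variance; full covariances are
singular when the number of samples exceeds the number of genes) are
selected by BIC, with ties broken toward fewer clusters.  Clusters below a
minimum size are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._gmm import fit_gmm_bic
from ._seeds import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class GeneCluster:
    """A within-dataset co-expressed gene set and (once filled) its PC1 metagene."""

    cluster_id: str
    source_dataset_id: str
    gene_ids: list[str]
    metagene: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.cluster_id}: duplicate gene ids")


def cluster_bimodal_genes(
    ds,
    bimodal_genes: list[str],
    k_max: int = 20,
    min_cluster_size: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
) -> list[GeneCluster]:
    """Partition a dataset's significantly bimodal genes into clusters.

    Returns clusters ordered by size descending, labelled
    ``<dataset_id>.c<ordinal>``.  Fewer bimodal genes than
    ``min_cluster_size`` yields an empty list with a warning.
    """
    genes = [g for g in bimodal_genes if g in set(ds.gene_ids)]
    if len(genes) < min_cluster_size:
        logger.warning(
            "%s: only %d bimodal gene(s); no clusters formed", ds.dataset_id, len(genes)
        )
        return []

    X = ds.values[ds.gene_index(genes)]
    # standardize each gene profile (rows are typically z-scored already)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)

    upper = max(1, min(k_max, len(genes) // min_cluster_size))
    labels, k, family, _ = fit_gmm_bic(
        X,
        k_max=upper,
        seed=derive_seed(seed, "gmm", ds.dataset_id),
        n_restarts=n_restarts,
    )
    logger.info("%s: BIC selected k=%d (%s covariance)", ds.dataset_id, k, family)

    groups = []
    for lab in range(k):
        members = [g for g, l in zip(genes, labels) if l == lab]
        if 0 < len(members) < min_cluster_size:
            logger.warning(
                "%s: discarding cluster of %d gene(s) below min size %d",
                ds.dataset_id, len(members), min_cluster_size,
            )
        elif members:
            groups.append(members)
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    return [
        GeneCluster(
            cluster_id=f"{ds.dataset_id}.c{i + 1}",
            source_dataset_id=ds.dataset_id,
            gene_ids=members,
        )
        for i, members in enumerate(groups)
    ]
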