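"""PC1 metagenes and projection scoring.

Each gene cluster is summarized by the unit-norm first principal axis of its
genes x samples submatrix in the dataset where it was discovered (genes as
variables, samples as observations).  A sample anywhere in the compendium is
then scored by the inner product of its z-scored expression over the cluster
genes with this weight vector.  The sign of the axis is chosen so that the
member genes correlate positively with the score on average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ClusterScoreMatrix:
    cluster_ids: list[str]
    sample_keys: list[tuple[str, str]]  # (dataset_id, sample_id)
    scores: np.ndarray  # clusters x samples

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cluster_ids), len(self.sample_keys)):
            raise ValueError("score matrix shape does not match id lists")
        if np.isnan(self.scores).any():
            raise ValueError("missing values in score matrix")


def pc1_weights(X: np.ndarray) -> np.ndarray:
    """Unit-norm first principal axis of a genes x samples matrix.

    Rows are assumed mean-centered (z-scored); the axis is the first left
    singular vector, oriented so the mean gene-score correlation is positive.
    Degenerate ties fall back to a positive first-gene weight with a warning.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    w = U[:, 0]
    if len(s) > 1 and abs(s[0] - s[1]) < 1e-12 * max(s[0], 1.0):
        logger.warning("PC1 degenerate (tied leading singular values); orienting by first gene")
        if w[0] < 0:
            w = -w
        return w
    scores = w @ X
    rsum = _gene_score_corr_sum(X, scores)
    if rsum < 0:
        w = -w
    elif rsum == 0 and w[0] < 0:
        w = -w
    return w


def _gene_score_corr_sum(X: np.ndarray, scores: np.ndarray) -> float:
    sv = scores - scores.mean()
    denom = np.linalg.norm(sv)
    if denom == 0:
        return 0.0
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    return float(((Xc[ok] @ sv) / (norms[ok] * denom)).sum())


def compute_metagene(cluster, origin) -> "GeneCluster":
    """Fill ``cluster.metagene`` with PC1 weights from its origin dataset."""
    missing = [g for g in cluster.gene_ids if g not in set(origin.gene_ids)]
    if missing:
        raise ValueError(
            f"{cluster.cluster_id}: genes absent from origin dataset: {missing[:5]}"
        )
    X = origin.values[origin.gene_index(cluster.gene_ids)]
    cluster.metagene = pc1_weights(X)
    return cluster


def score_samples(cluster, ds, return_retained: bool = False):
    """Project a dataset's samples onto a cluster metagene.

    Genes absent from ``ds`` contribute nothing; the retained fraction of the
    weight-vector norm is logged (warning below 0.5) and optionally returned.
    """
    if cluster.metagene is None:
        raise ValueError(f"{cluster.cluster_id}: metagene not computed")
    present = [i for i, g in enumerate(cluster.gene_ids) if g in set(ds.gene_ids)]
    if not present:
        raise ValueError(
            f"{cluster.cluster_id}: no metagene gene present in {ds.dataset_id}"
        )
    w = cluster.metagene[present]
    genes = [cluster.gene_ids[i] for i in present]
    retained = float(np.linalg.norm(w))
    if retained < 0.5:
        logger.warning(
            "%s on %s: only %.2f of metagene norm retained",
            cluster.cluster_id, ds.dataset_id, retained,
        )
    scores = w @ ds.values[ds.gene_index(genes)]
    if return_retained:
        return scores, retained
    return scores


def score_compendium(clusters, comp) -> ClusterScoreMatrix:
    """Score every sample of a compendium against every cluster metagene.

    Datasets are assumed preprocessed (independently z-scored); scores are
    concatenated over datasets in compendium order.
    """
    sample_keys = [
        (ds.dataset_id, s) for ds in comp.datasets for s in ds.sample_ids
    ]
    rows = []
    for cl in clusters:
        parts = [score_samples(cl, ds) for ds in comp.datasets]
        rows.append(np.concatenate(parts))
    return ClusterScoreMatrix(
        cluster_ids=[cl.cluster_id for cl in clusters],
        sample_keys=sample_keys,
        scores=np.vstack(rows) if rows else np.zeros((0, len(sample_keys))),
    )
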