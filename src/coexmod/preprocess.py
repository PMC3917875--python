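"""Expression containers and per-dataset normalization.

Each dataset is handled independently throughout the pipeline: genes are
z-scored within a dataset, a per-array quality score (``avg_z``, the mean of
the gene-wise z-scores on each array) is computed, and every gene is replaced
by the residual of an ordinary least-squares regression on that quality
score.  This removes array-quality-driven correlation between genes before
any co-expression analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

CONTEXTS = ("tumor", "cell_line", "mixed")


@dataclass
class ExpressionDataset:
    """One dataset's genes x samples log2 expression matrix.

    Parameters
    ----------
    dataset_id : str
        Unique identifier for the dataset.
    context : str
        One of ``tumor``, ``cell_line`` or ``mixed``.
    gene_ids, sample_ids : list of str
        Row and column labels; both must be unique.
    values : ndarray, shape (n_genes, n_samples)
        Log2-scale expression.
    avg_z : ndarray or None
        Per-sample quality score, filled by :func:`compute_avg_z`.
    """

    dataset_id: str
    context: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    avg_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.dataset_id}: duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError(f"{self.dataset_id}: missing values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        idx = self.gene_index(gene_ids)
        return replace(self, gene_ids=list(gene_ids), values=self.values[idx], avg_z=self.avg_z)


@dataclass
class Compendium:
    """A list of datasets restricted to a shared, identically ordered gene universe."""

    datasets: list[ExpressionDataset]
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ds in self.datasets:
            if ds.gene_ids != self.gene_universe:
                raise ValueError(f"{ds.dataset_id}: gene ids differ from gene universe")

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def get(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)


def restrict_to_common_genes(datasets: list[ExpressionDataset]) -> Compendium:
    """Restrict all datasets to their common genes, sorted lexicographically.

    Raises
    ------
    ValueError
        If no datasets are given or the intersection of gene sets is empty.
    """
    if not datasets:
        raise ValueError("no datasets given")
    for ds in datasets:
        if ds.n_genes < 2:
            raise ValueError(f"{ds.dataset_id}: fewer than 2 genes")
    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        ids = ", ".join(ds.dataset_id for ds in datasets)
        raise ValueError(f"empty gene intersection across datasets: {ids}")
    universe = sorted(common)
    return Compendium([ds.subset_genes(universe) for ds in datasets], universe)


def zscore_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each gene row (sample sd, n-1 denominator); drop constant genes."""
    if ds.n_samples < 3:
        raise ValueError(f"{ds.dataset_id}: need >= 3 samples to z-score")
    mu = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [g for g, k in zip(ds.gene_ids, keep) if not k]
        logger.warning(
            "%s: dropping %d zero-variance gene(s): %s%s",
            ds.dataset_id, len(dropped), ", ".join(dropped[:5]),
            " ..." if len(dropped) > 5 else "",
        )
    z = (ds.values[keep] - mu[keep]) / sd[keep]
    return replace(
        ds,
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        values=z,
        avg_z=ds.avg_z,
    )


def compute_avg_z(ds: ExpressionDataset) -> np.ndarray:
    """Per-array quality score: mean over genes of the z-scored expression.

    The dataset is expected to be z-scored already.  The result is stored on
    the dataset (``ds.avg_z``) and returned.
    """
    avg_z = ds.values.mean(axis=0)
    ds.avg_z = avg_z
    return avg_z


def quality_adjust(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace every gene row by its OLS residual on (intercept, avg_z).

    Additive per-array effects shared across genes are removed exactly; every
    output row has mean 0 and is numerically orthogonal to ``avg_z``.  If
    ``avg_z`` is constant the adjustment is skipped with a warning.
    """
    if ds.avg_z is None:
        raise ValueError(f"{ds.dataset_id}: avg_z not computed")
    q = np.asarray(ds.avg_z, dtype=float)
    qc = q - q.mean()
    denom = qc @ qc
    if denom <= 0:
        logger.warning("%s: avg_z constant; skipping quality adjustment", ds.dataset_id)
        return ds
    X = ds.values
    # residual of row on (1, q): subtract row mean and projection on centered q
    Xc = X - X.mean(axis=1, keepdims=True)
    beta = (Xc @ qc) / denom
    resid = Xc - np.outer(beta, qc)
    return replace(ds, values=resid, avg_z=q)


def preprocess_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Full per-dataset normalization: z-score, avg_z, residualize, re-z-score.

    The second z-scoring restores unit variance after residualization so that
    downstream metagene projections use unit-variance inputs.
    """
    z = zscore_genes(ds)
    compute_avg_z(z)
    adj = quality_adjust(z)
    out = zscore_genes(adj)
    out.avg_z = adj.avg_z
    return out


def median_collapse(ds: ExpressionDataset, gene_to_symbol: dict[str, str]) -> ExpressionDataset:
    """Collapse probe-level rows to gene symbols by the per-sample median.

    Used before scoring cross-platform datasets whose row identifiers are
    probes: rows mapping to the same symbol are replaced by their median
    profile; rows without a mapping are dropped.  Output rows are sorted by
    symbol.
    """
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(ds.gene_ids):
        sym = gene_to_symbol.get(g)
        if sym is not None:
            groups.setdefault(sym, []).append(i)
    if not groups:
        raise ValueError(f"{ds.dataset_id}: no rows map to a gene symbol")
    symbols = sorted(groups)
    values = np.vstack([np.median(ds.values[groups[s]], axis=0) for s in symbols])
    return replace(ds, gene_ids=symbols, values=values, avg_z=None)


def preprocess_compendium(comp: Compendium) -> Compendium:
    """Preprocess each dataset; re-restrict in case constant genes were dropped."""
    processed = [preprocess_dataset(ds) for ds in comp.datasets]
    return restrict_to_common_genes(processed)
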