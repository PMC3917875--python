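"""Readers and writers for the package's plain-text interchange formats.

Expression matrices travel as TSV with a ``gene_id`` first column and sample
ids in the header; gene sets as GMT (set name, description, tab-separated
gene ids); module weights as (module_id, gene_id, weight) TSV; clinical
annotation as a flat TSV.  All files are UTF-8, tab-separated, unquoted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionDataset

logger = logging.getLogger(__name__)


def read_expression_tsv(path, dataset_id: str | None = None, context: str = "tumor") -> ExpressionDataset:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {header[0]!r}")
    if len(set(header[1:])) != len(header) - 1:
        raise ValueError(f"{path}: duplicate sample ids in header")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 2  # header is line 1
        raise ValueError(f"{path}: malformed/ragged row at line {bad}")
    genes = df["gene_id"].tolist()
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        lines = [i + 2 for i, g in enumerate(genes) if g in set(dupes)]
        raise ValueError(f"{path}: duplicate gene ids {sorted(set(dupes))[:5]} at lines {lines[:10]}")
    samples = [str(c) for c in df.columns[1:]]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        context=context,
        gene_ids=genes,
        sample_ids=samples,
        values=values,
    )


def write_expression_tsv(ds: ExpressionDataset, path) -> None:
    df = pd.DataFrame(ds.values, index=pd.Index(ds.gene_ids, name="gene_id"), columns=ds.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_manifest_tsv(path) -> pd.DataFrame:
    """Dataset manifest: columns dataset_id, path, context."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "path", "context"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: GMT line needs name, description, >=1 gene")
            name, genes = fields[0], fields[2:]
            if name in sets:
                raise ValueError(f"{path}: line {ln}: duplicate set name {name!r}")
            seen, uniq = set(), []
            for g in genes:
                if g in seen:
                    logger.warning("%s: line %d: duplicate gene %r in set %r; de-duplicated", path, ln, g, name)
                else:
                    seen.add(g)
                    uniq.append(g)
            sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "coexmod") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_weights_tsv(path) -> dict[str, dict[str, float]]:
    """Module weight table: columns module_id, gene_id, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "gene_id": str})
    out: dict[str, dict[str, float]] = {}
    for mod, grp in df.groupby("module_id", sort=True):
        if grp["gene_id"].duplicated().any():
            raise ValueError(f"{path}: duplicate gene in module {mod}")
        out[mod] = dict(zip(grp["gene_id"], grp["weight"].astype(float)))
    return out


def write_weights_tsv(modules, path) -> None:
    rows = [
        {"module_id": m.module_id, "gene_id": g, "weight": w}
        for m in modules
        for g, w in zip(m.gene_ids, np.asarray(m.weights))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_scores_tsv(score_matrix, path) -> None:
    """Cluster/module score matrix as TSV with dataset:sample column keys."""
    if hasattr(score_matrix, "sample_keys"):
        cols = [f"{d}:{s}" for d, s in score_matrix.sample_keys]
        index = pd.Index(score_matrix.cluster_ids, name="cluster_id")
    else:
        cols = score_matrix.sample_ids
        index = pd.Index(score_matrix.module_ids, name="module_id")
    pd.DataFrame(score_matrix.scores, index=index, columns=cols).to_csv(
        path, sep="\t", float_format="%.10g"
    )
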