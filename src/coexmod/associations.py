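"""Downstream statistics on module scores.

Covers: module coherence (all-pairs gene correlations, Fisher z), the
tumor-intrinsic vs microenvironment-extrinsic classification rule, subtype
prediction AUC with Youden-optimal thresholds, published-signature scoring
and module-signature correlation, and clinical association models (Cox
proportional hazards for recurrence-free survival, logistic regression for
pathologic complete response and bone-only metastasis), with
Benjamini-Hochberg adjustment across modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bimodality import bh_fdr
from .consensus import Module, score_module
from .preprocess import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class CoherenceRecord:
    module_id: str
    context: str
    pairwise_r: np.ndarray
    mean_fisher_z: float
    mean_r_back: float  # tanh of the mean Fisher z
    median_r: float
    score_variance: float


@dataclass
class AUCRecord:
    module_id: str
    label_name: str
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float


@dataclass
class SignatureDef:
    """A published gene signature: +/-1-weighted mean or centroid correlation."""

    name: str
    type: str  # "weighted_mean" | "centroid"
    gene_weights: dict[str, float] | None = None
    centroid: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.type not in ("weighted_mean", "centroid"):
            raise ValueError(f"unknown signature type {self.type!r}")
        table = self.gene_weights if self.type == "weighted_mean" else self.centroid
        if not table:
            raise ValueError(f"signature {self.name}: empty gene set")


@dataclass
class AssociationRecord:
    module_id: str
    model: str  # cox | logistic | ttest | ftest
    estimate: float
    p: float
    q: float = np.nan
    covariates: list[str] = field(default_factory=list)
    converged: bool = True
    note: str = ""


# ---------------------------------------------------------------- coherence

def coherence_stats(module: Module, ds: ExpressionDataset) -> CoherenceRecord:
    """All-pairs Pearson correlation of module genes in one dataset.

    Fisher z = atanh(r) with r clipped just inside +/-1; the record carries
    the mean z, its back-transform, the median r, and the variance of the
    module score in this dataset.
    """
    present = [g for g in module.gene_ids if g in set(ds.gene_ids)]
    if len(present) < 2:
        raise ValueError(f"{module.module_id}: fewer than 2 module genes in {ds.dataset_id}")
    X = ds.values[ds.gene_index(present)]
    corr = np.corrcoef(X)
    iu = np.triu_indices(len(present), k=1)
    r = np.clip(corr[iu], -(1 - 1e-12), 1 - 1e-12)
    z = np.arctanh(r)
    scores = score_module(module, ds)
    return CoherenceRecord(
        module_id=module.module_id,
        context=ds.context,
        pairwise_r=r,
        mean_fisher_z=float(z.mean()),
        mean_r_back=float(np.tanh(z.mean())),
        median_r=float(np.median(r)),
        score_variance=float(np.var(scores, ddof=1)),
    )


def compare_coherence(a: CoherenceRecord, b: CoherenceRecord) -> AssociationRecord:
    """Welch t-test on the Fisher-transformed correlation vectors."""
    if a.module_id != b.module_id:
        raise ValueError("records refer to different modules")
    za, zb = np.arctanh(np.clip(a.pairwise_r, -(1 - 1e-12), 1 - 1e-12)), np.arctanh(
        np.clip(b.pairwise_r, -(1 - 1e-12), 1 - 1e-12)
    )
    if len(za) < 2 or len(zb) < 2:
        raise ValueError("need at least 2 gene pairs per context")
    t = stats.ttest_ind(za, zb, equal_var=False)
    return AssociationRecord(
        module_id=a.module_id,
        model="ttest",
        estimate=float(za.mean() - zb.mean()),
        p=float(t.pvalue),
        covariates=[f"{a.context}_vs_{b.context}"],
    )


def compare_score_variance(
    module: Module, a: ExpressionDataset, b: ExpressionDataset
) -> AssociationRecord:
    """Two-sided F-test comparing module-score variances in two datasets."""
    sa, sb = score_module(module, a), score_module(module, b)
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("need at least 3 samples per dataset")
    va, vb = np.var(sa, ddof=1), np.var(sb, ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator dataset")
    F = va / vb
    dfa, dfb = len(sa) - 1, len(sb) - 1
    cdf = stats.f.cdf(F, dfa, dfb)
    p = float(2 * min(cdf, 1 - cdf))
    return AssociationRecord(
        module_id=module.module_id,
        model="ftest",
        estimate=float(F),
        p=min(p, 1.0),
        covariates=[a.dataset_id, b.dataset_id],
    )


def classify_intrinsic_extrinsic(tumor: CoherenceRecord, cellline: CoherenceRecord) -> str:
    """Extrinsic: incoherent in cell lines (mean r < 0.1) but coherent in
    tumors (median r > 0.35); intrinsic: coherent in both; else indeterminate."""
    if cellline.mean_r_back < 0.1 and tumor.median_r > 0.35:
        return "extrinsic"
    if tumor.median_r > 0.35 and cellline.median_r > 0.35:
        return "intrinsic"
    return "indeterminate"


# ----------------------------------------------------------------- ROC/AUC

def subtype_auc(scores: np.ndarray, label: np.ndarray, module_id: str = "", label_name: str = "") -> AUCRecord:
    """AUC by the rank (Mann-Whitney) formula with the Youden-optimal cut.

    Higher scores predict the positive class.  The threshold t maximizing
    sensitivity + specificity - 1 (prediction positive iff score >= t) is
    searched over the observed scores; ties prefer higher specificity, then
    the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    label = np.asarray(label).astype(int)
    n_pos, n_neg = int(label.sum()), int((1 - label).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(scores)
    auc = (ranks[label == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    best = None  # (J, specificity, threshold, sensitivity)
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (label == 1)).sum() / n_pos
        spec = (~pred & (label == 0)).sum() / n_neg
        cand = (sens + spec - 1.0, spec, t, sens)
        if best is None or cand[:3] > best[:3]:
            best = cand
    j, spec, thr, sens = best
    return AUCRecord(
        module_id=module_id,
        label_name=label_name,
        auc=float(auc),
        youden_threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
    )


# -------------------------------------------------------------- signatures

def signature_score(ds: ExpressionDataset, sig: SignatureDef) -> np.ndarray:
    """Score samples for a published signature.

    weighted_mean: mean over present genes of weight * z(g, s) (weights +/-1
    by direction of association with outcome).  centroid: per-sample Pearson
    correlation between the sample's expression over signature genes and the
    centroid profile.
    """
    table = sig.gene_weights if sig.type == "weighted_mean" else sig.centroid
    present = [g for g in table if g in set(ds.gene_ids)]
    if not present:
        raise ValueError(f"signature {sig.name}: no genes present in {ds.dataset_id}")
    X = ds.values[ds.gene_index(present)]
    vals = np.array([table[g] for g in present])
    if sig.type == "weighted_mean":
        return (vals[:, None] * X).mean(axis=0)
    if len(present) < 3:
        raise ValueError(f"signature {sig.name}: centroid needs >= 3 genes present")
    Xc = X - X.mean(axis=0, keepdims=True)
    vc = vals - vals.mean()
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(vc)
    if (denom == 0).any():
        raise ValueError(f"signature {sig.name}: zero-variance sample profile")
    return (vc @ Xc) / denom


def module_signature_correlation(mscores: np.ndarray, sscores: np.ndarray) -> float:
    """Pearson r between module and signature scores."""
    mscores, sscores = np.asarray(mscores, float), np.asarray(sscores, float)
    if len(mscores) != len(sscores) or len(mscores) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if mscores.std() == 0 or sscores.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(mscores, sscores)[0, 1])


def dichotomize(scores: np.ndarray, rule: str = "median") -> np.ndarray:
    """median: high iff score > median; lower_tertile: low iff score <= the
    33.33rd percentile (linear interpolation)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 scores")
    if rule == "median":
        return (scores > np.median(scores)).astype(int)
    if rule == "lower_tertile":
        cut = np.percentile(scores, 100.0 / 3.0)
        return (scores <= cut).astype(int)
    raise ValueError(f"unknown rule {rule!r}")


# --------------------------------------------------------- clinical models

def cox_association(
    scores: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[AssociationRecord]:
    """Per-module Cox proportional-hazards fit (Efron ties) with BH q-values.

    ``scores`` holds one column per module; each module is fit in its own
    model together with the optional covariate columns.  Estimates are
    log-hazard-ratios per unit score with Wald p-values.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    if event.sum() < 10:
        raise ValueError("need at least 10 events")
    records = []
    cov_names = list(covariates.columns) if covariates is not None else []
    for mod in scores.columns:
        col = scores[mod].to_numpy(dtype=float)
        if col.std(ddof=1) == 0:
            raise ValueError(f"{mod}: zero-variance score column")
        df = pd.DataFrame({"time": time, "event": event, mod: col})
        if covariates is not None:
            for c in cov_names:
                df[c] = covariates[c].to_numpy()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            records.append(
                AssociationRecord(
                    module_id=mod,
                    model="cox",
                    estimate=float(cph.params_[mod]),
                    p=float(cph.summary.loc[mod, "p"]),
                    covariates=cov_names,
                )
            )
        except ConvergenceError as err:
            logger.warning("%s: Cox fit did not converge: %s", mod, err)
            records.append(
                AssociationRecord(
                    module_id=mod, model="cox", estimate=np.nan, p=1.0,
                    covariates=cov_names, converged=False, note=str(err),
                )
            )
    _attach_q(records)
    return records


def logistic_response(
    scores: pd.DataFrame,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[AssociationRecord]:
    """Per-module logistic regression (e.g. pCR, bone-only metastasis).

    Reports log-odds-ratios with Wald p and BH q across modules; perfect
    separation yields a flagged, non-converged record.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    outcome = np.asarray(outcome).astype(int)
    if outcome.sum() < 5 or (1 - outcome).sum() < 5:
        raise ValueError("need at least 5 samples in each outcome class")
    records = []
    cov_names = list(covariates.columns) if covariates is not None else []
    for mod in scores.columns:
        X = pd.DataFrame({mod: scores[mod].to_numpy(dtype=float)})
        for c in cov_names:
            X[c] = covariates[c].to_numpy()
        X = sm.add_constant(X)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                raise PerfectSeparationError("logistic fit did not converge")
            records.append(
                AssociationRecord(
                    module_id=mod,
                    model="logistic",
                    estimate=float(fit.params[mod]),
                    p=float(fit.pvalues[mod]),
                    covariates=cov_names,
                )
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as err:
            logger.warning("%s: logistic fit failed: %s", mod, err)
            records.append(
                AssociationRecord(
                    module_id=mod, model="logistic", estimate=np.nan, p=1.0,
                    covariates=cov_names, converged=False, note=str(err),
                )
            )
    _attach_q(records)
    return records


def model_auc(scores: pd.DataFrame, outcome: np.ndarray) -> float:
    """In-sample AUC of a multivariate logistic model's fitted probabilities."""
    import statsmodels.api as sm

    X = sm.add_constant(scores.astype(float))
    fit = sm.Logit(np.asarray(outcome).astype(int), X).fit(disp=0, maxiter=200)
    rec = subtype_auc(fit.predict(X), outcome)
    return rec.auc


def group_mean_difference(scores: np.ndarray, groups: np.ndarray, module_id: str = "") -> AssociationRecord:
    """Welch t-test for a module-score difference between two groups."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups).astype(int)
    a, b = scores[groups == 1], scores[groups == 0]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 samples")
    t = stats.ttest_ind(a, b, equal_var=False)
    return AssociationRecord(
        module_id=module_id,
        model="ttest",
        estimate=float(a.mean() - b.mean()),
        p=float(t.pvalue),
    )


def adjust_records(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """BH-adjust p-values across a set of association records (shared bh_fdr)."""
    _attach_q(records)
    return records


def _attach_q(records: list[AssociationRecord]) -> None:
    if not records:
        return
    q = bh_fdr(np.array([max(min(r.p, 1.0), np.finfo(float).tiny) for r in records]))
    for r, qi in zip(records, q):
        r.q = float(max(qi, r.p))


def pool_datasets(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Mean-center each gene within each dataset, then concatenate samples.

    Sample ids are prefixed ``dataset_id:`` to keep provenance; context is
    'mixed' unless all sources share one context.
    """
    if not datasets:
        raise ValueError("no datasets to pool")
    universe = datasets[0].gene_ids
    for ds in datasets[1:]:
        if ds.gene_ids != universe:
            raise ValueError(f"{ds.dataset_id}: gene universe mismatch")
    blocks, sample_ids = [], []
    for ds in datasets:
        blocks.append(ds.values - ds.values.mean(axis=1, keepdims=True))
        sample_ids += [f"{ds.dataset_id}:{s}" for s in ds.sample_ids]
    contexts = {ds.context for ds in datasets}
    return ExpressionDataset(
        dataset_id="+".join(ds.dataset_id for ds in datasets),
        context=contexts.pop() if len(contexts) == 1 else "mixed",
        gene_ids=list(universe),
        sample_ids=sample_ids,
        values=np.hstack(blocks),
    )
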