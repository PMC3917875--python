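"""SigClust: Monte-Carlo significance of a 2-way partition.

The cluster index CI is the ratio of within-cluster to total sum of squared
distances about the respective means.  Under the null hypothesis the data
are a single multivariate Gaussian; its covariance eigenvalues are estimated
from the data with a background-noise floor sigma_N^2 (MAD-based), using
either hard thresholding (eigenvalues floored at sigma_N^2) or soft
thresholding (eigenvalues shifted down by a common tau, floored at
sigma_N^2, with tau chosen to preserve the total variance when attainable).
Null datasets are simulated in the covariance eigenbasis — CI is rotation
invariant — partitioned by 2-means (best of restarts), and an add-one
empirical p-value is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit
from scipy.stats import norm

from ._seeds import derive_seed

logger = logging.getLogger(__name__)

_MAD_CONST = norm.ppf(0.75)  # ~0.6745


@dataclass
class SigClustResult:
    pair: tuple[str, str]
    ci_observed: float
    null_ci: np.ndarray
    p_value: float
    method: str
    n_sims: int
    seed: int
    sigma_n2: float
    null_eigenvalues: np.ndarray


def cluster_index(data: np.ndarray, labels: np.ndarray) -> float:
    """CI = within-2-cluster SS / total SS about the grand mean, in [0, 1]."""
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 observations")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    total = float(((data - data.mean(axis=0)) ** 2).sum())
    if total == 0:
        raise ValueError("total sum of squares is zero (all points identical)")
    within = 0.0
    for c in classes:
        block = data[labels == c]
        within += float(((block - block.mean(axis=0)) ** 2).sum())
    return within / total


def estimate_null_eigenvalues(data: np.ndarray, method: str = "hard") -> tuple[float, np.ndarray]:
    """Background noise variance and thresholded covariance eigenvalues.

    sigma_N^2 = (MAD of the column-mean-centered entries / Phi^-1(0.75))^2.
    hard: lambda_j -> max(lambda_j, sigma_N^2).
    soft: lambda_j -> max(lambda_j - tau, sigma_N^2) with tau >= 0 solving
    sum lambda~ = sum lambda (total variance preserved); if even the floor
    alone exceeds the total variance, all eigenvalues are set to sigma_N^2.
    """
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    if n < 3 or d < 1:
        raise ValueError("need >= 3 observations and >= 1 feature")
    centered = data - data.mean(axis=0)
    mad = np.median(np.abs(centered - np.median(centered)))
    if mad == 0:
        raise ValueError("degenerate data: zero MAD")
    sigma_n2 = float((mad / _MAD_CONST) ** 2)
    cov = np.cov(data, rowvar=False)
    cov = np.atleast_2d(cov)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 0.0, None)

    if method == "hard":
        lam_t = np.maximum(lam, sigma_n2)
    elif method == "soft":
        target = lam.sum()
        if target <= d * sigma_n2:
            lam_t = np.full(d, sigma_n2)
        else:
            lam_t = _soft_threshold(lam, sigma_n2, target)
    else:
        raise ValueError(f"unknown method {method!r}")
    return sigma_n2, lam_t


def _soft_threshold(lam: np.ndarray, sigma_n2: float, target: float) -> np.ndarray:
    """Solve for tau >= 0 with sum(max(lam - tau, sigma_n2)) = target.

    f(tau) is piecewise linear and nonincreasing; the exact breakpoints are
    tau_j = lam_j - sigma_n2, so the solution is found in closed form.
    """
    def f(tau: float) -> float:
        return float(np.maximum(lam - tau, sigma_n2).sum())

    if f(0.0) <= target:  # flooring alone does not inflate: keep tau = 0
        return np.maximum(lam, sigma_n2)
    breaks = np.sort(np.clip(lam - sigma_n2, 0.0, None))
    lo = 0.0
    for b in breaks:
        if f(b) <= target:
            hi = b
            break
        lo = b
    else:
        hi = breaks[-1]
    # linear on [lo, hi]: interpolate exactly
    flo, fhi = f(lo), f(hi)
    tau = lo if flo == fhi else lo + (flo - target) * (hi - lo) / (flo - fhi)
    return np.maximum(lam - tau, sigma_n2)


@njit(cache=True)
def _two_means_kernel(data, init_pairs):  # pragma: no cover - numba kernel
    """Lloyd 2-means from each initial point pair; return labels with minimal CI.

    Returns (labels, ci); ci = inf if every restart collapsed to one cluster.
    """
    n, d = data.shape
    grand = np.zeros(d)
    for i in range(n):
        grand += data[i]
    grand /= n
    total = 0.0
    for i in range(n):
        for k in range(d):
            diff = data[i, k] - grand[k]
            total += diff * diff
    best_ci = np.inf
    best_labels = np.zeros(n, dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    for r in range(init_pairs.shape[0]):
        c0 = data[init_pairs[r, 0]].copy()
        c1 = data[init_pairs[r, 1]].copy()
        for i in range(n):
            labels[i] = -1
        for _ in range(100):
            changed = False
            n0 = 0
            for i in range(n):
                d0 = 0.0
                d1 = 0.0
                for k in range(d):
                    t0 = data[i, k] - c0[k]
                    t1 = data[i, k] - c1[k]
                    d0 += t0 * t0
                    d1 += t1 * t1
                lab = 0 if d0 <= d1 else 1
                if lab != labels[i]:
                    changed = True
                labels[i] = lab
                if lab == 0:
                    n0 += 1
            if not changed:
                break
            if n0 > 0:
                for k in range(d):
                    c0[k] = 0.0
                for i in range(n):
                    if labels[i] == 0:
                        for k in range(d):
                            c0[k] += data[i, k]
                for k in range(d):
                    c0[k] /= n0
            if n0 < n:
                for k in range(d):
                    c1[k] = 0.0
                for i in range(n):
                    if labels[i] == 1:
                        for k in range(d):
                            c1[k] += data[i, k]
                for k in range(d):
                    c1[k] /= n - n0
        n0 = 0
        for i in range(n):
            if labels[i] == 0:
                n0 += 1
        if n0 == 0 or n0 == n:
            continue
        # within-cluster SS about the two means
        for k in range(d):
            c0[k] = 0.0
            c1[k] = 0.0
        for i in range(n):
            if labels[i] == 0:
                for k in range(d):
                    c0[k] += data[i, k]
            else:
                for k in range(d):
                    c1[k] += data[i, k]
        for k in range(d):
            c0[k] /= n0
            c1[k] /= n - n0
        within = 0.0
        for i in range(n):
            if labels[i] == 0:
                for k in range(d):
                    diff = data[i, k] - c0[k]
                    within += diff * diff
            else:
                for k in range(d):
                    diff = data[i, k] - c1[k]
                    within += diff * diff
        ci = within / total
        if ci < best_ci:
            best_ci = ci
            best_labels = labels.copy()
    return best_labels, best_ci


def two_means_labels(
    data: np.ndarray, rng: np.random.Generator, n_restarts: int = 10
) -> np.ndarray:
    """Best 2-means partition (minimal CI) over restarts with random pair init."""
    data = np.ascontiguousarray(data, dtype=float)
    n = data.shape[0]
    pairs = np.empty((n_restarts, 2), dtype=np.int64)
    for r in range(n_restarts):
        pairs[r] = rng.choice(n, size=2, replace=False)
    labels, ci = _two_means_kernel(data, pairs)
    if not np.isfinite(ci):  # all restarts degenerate; split on first coordinate
        labels = (data[:, 0] > np.median(data[:, 0])).astype(np.int64)
    return labels


def _two_means_ci(data: np.ndarray, rng: np.random.Generator, n_restarts: int = 10) -> float:
    labels = two_means_labels(data, rng, n_restarts)
    if len(np.unique(labels)) < 2:
        return 1.0
    return cluster_index(data, labels)


def sigclust_pvalue(
    data: np.ndarray,
    labels: np.ndarray | None = None,
    method: str = "hard",
    n_sims: int = 1000,
    seed: int = 0,
    pair: tuple[str, str] = ("a", "b"),
) -> SigClustResult:
    """Empirical SigClust p-value for an observed 2-way partition.

    With ``labels=None`` the observed partition is itself found by 2-means
    (best of 10 seeded restarts), matching the treatment of the null sets.
    Null datasets are independent normals scaled by the square roots of the
    thresholded eigenvalues (simulating directly in the eigenbasis), each
    partitioned by 2-means with 10 seeded restarts.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    if labels is None:
        labels = two_means_labels(
            data, np.random.default_rng(derive_seed(seed, "sigclust_obs", method, *pair))
        )
    ci_obs = cluster_index(data, labels)
    sigma_n2, lam = estimate_null_eigenvalues(data, method)
    sd = np.sqrt(lam)
    rng = np.random.default_rng(derive_seed(seed, "sigclust", method, *pair))
    null_ci = np.empty(n_sims)
    for b in range(n_sims):
        sim = rng.standard_normal((n, d)) * sd
        null_ci[b] = _two_means_ci(sim, rng)
    p = (1 + int((null_ci <= ci_obs).sum())) / (n_sims + 1)
    return SigClustResult(
        pair=pair,
        ci_observed=float(ci_obs),
        null_ci=null_ci,
        p_value=float(p),
        method=method,
        n_sims=n_sims,
        seed=seed,
        sigma_n2=sigma_n2,
        null_eigenvalues=lam,
    )


def pairwise_module_sigclust(
    assignment: dict,
    corr: np.ndarray,
    cluster_ids: list[str],
    method: str = "hard",
    n_sims: int = 1000,
    seed: int = 0,
) -> list[SigClustResult]:
    """SigClust on every unordered module pair.

    Observations are the member clusters' rows of the score-correlation
    matrix (the same feature space used to define the modules); labels are
    the module assignment itself.  Modules with a single member cluster are
    skipped with a warning.
    """
    corr = np.asarray(corr, dtype=float)
    idx = {cid: i for i, cid in enumerate(cluster_ids)}
    members: dict[str, list[int]] = {}
    for cid, mod in assignment.items():
        members.setdefault(mod, []).append(idx[cid])
    mods = sorted(members)
    if len(mods) < 2:
        raise ValueError("need at least 2 modules")
    results = []
    for a, b in combinations(mods, 2):
        if len(members[a]) < 2 or len(members[b]) < 2:
            logger.warning("skipping pair (%s, %s): single-member module", a, b)
            continue
        rows = members[a] + members[b]
        data = corr[rows]
        labels = np.array([0] * len(members[a]) + [1] * len(members[b]))
        results.append(
            sigclust_pvalue(data, labels, method=method, n_sims=n_sims, seed=seed, pair=(a, b))
        )
    return results
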