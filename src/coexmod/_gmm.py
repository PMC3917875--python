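"""Diagonal-family Gaussian mixtures for gene clustering.

Model selection over the four diagonal/spherical covariance families used in
model-based clustering, in the standard naming scheme:

    EII  spherical, one variance shared by all components
    VII  spherical, one variance per component
    EEI  diagonal, one variance vector shared by all components
    VVI  diagonal, one variance vector per component

The equal-variance families matter: with few observations (genes) in many
dimensions (samples), per-component variances let small clusters shrink
their variance and BIC then over-splits; the shared-variance families keep
the penalty honest.  Full-covariance families are excluded because the
feature dimension routinely exceeds the observation count.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import kmeans_plusplus

FAMILIES = ("EII", "VII", "EEI", "VVI")

_LOG2PI = float(np.log(2.0 * np.pi))


def _n_params(family: str, k: int, d: int) -> int:
    mean_params = k * d
    prop_params = k - 1
    var_params = {"EII": 1, "VII": k, "EEI": d, "VVI": k * d}[family]
    return mean_params + prop_params + var_params


def _estep(X, pi, means, variances):
    """Log-responsibilities and total log-likelihood.

    ``variances`` has shape (k, d) (broadcast from the family's M-step).
    """
    # log N(x | mu_k, diag(v_k)) for all points and components
    inv = 1.0 / variances  # (k, d)
    quad = (
        (X**2) @ inv.T
        - 2.0 * X @ (means * inv).T
        + ((means**2) * inv).sum(axis=1)
    )  # (n, k)
    logdet = np.log(variances).sum(axis=1)  # (k,)
    logp = -0.5 * (quad + logdet + X.shape[1] * _LOG2PI) + np.log(pi)
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    return logp - lse[:, None], float(lse.sum())


def _mstep(X, R, family, var_floor):
    n, d = X.shape
    k = R.shape[1]
    nk = R.sum(axis=0) + 1e-10
    pi = nk / n
    means = (R.T @ X) / nk[:, None]
    sq = (R.T @ (X**2)) / nk[:, None] - means**2  # per component per feature
    sq = np.maximum(sq, 0.0)
    if family == "VVI":
        var = sq
    elif family == "EEI":
        var = np.tile((sq * nk[:, None]).sum(axis=0) / n, (k, 1))
    elif family == "VII":
        var = np.tile(sq.mean(axis=1)[:, None], (1, d))
    else:  # EII
        var = np.full((k, d), (sq * nk[:, None]).sum() / (n * d))
    return pi, means, np.maximum(var, var_floor)


def _fit_once(X, k, family, rng, var_floor, max_iter=300, tol=1e-7):
    n, d = X.shape
    if k == 1:
        R = np.ones((n, 1))
        pi, means, var = _mstep(X, R, family, var_floor)
        _, ll = _estep(X, pi, means, var)
        return ll, pi, means, var
    centers, _ = kmeans_plusplus(
        X, n_clusters=k, random_state=int(rng.integers(2**31))
    )
    assign = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    R = np.zeros((n, k))
    R[np.arange(n), assign] = 1.0
    R = R + 1e-6  # soften so empty components recover
    R /= R.sum(axis=1, keepdims=True)
    ll_prev = -np.inf
    for _ in range(max_iter):
        pi, means, var = _mstep(X, R, family, var_floor)
        logR, ll = _estep(X, pi, means, var)
        R = np.exp(logR)
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            break
        ll_prev = ll
    # reject singular solutions (near-empty components or collapsed variance):
    # the mixture MLE is unbounded in high dimensions, and such fits would
    # otherwise dominate BIC spuriously
    if (pi * n < 2.0 - 1e-9).any() or (var <= 2.0 * var_floor).any():
        return -np.inf, pi, means, var
    return ll, pi, means, var


def fit_gmm_bic(
    X: np.ndarray,
    k_max: int,
    seed: int,
    n_restarts: int = 5,
    families: tuple[str, ...] = FAMILIES,
    patience: int = 4,
):
    """Select (k, family) by BIC and return hard assignments.

    BIC = loglik - (params/2) ln(n); ties resolved toward smaller k by strict
    improvement while scanning k upward.  Per family, the scan stops after
    ``patience`` consecutive k without improvement.  Returns
    (labels, k, family, bic).
    """
    X = np.ascontiguousarray(X, dtype=float)
    n, d = X.shape
    var_floor = 1e-6 * float(X.var())
    best = None  # (bic, k, family index, params)
    rng_master = np.random.default_rng(seed)
    restart_seeds = rng_master.integers(2**31, size=(len(families), k_max, n_restarts))
    for fi, family in enumerate(families):
        best_fam = -np.inf
        stale = 0
        for k in range(1, k_max + 1):
            ll_best, params_best = -np.inf, None
            for r in range(n_restarts):
                rng = np.random.default_rng(int(restart_seeds[fi, k - 1, r]))
                ll, pi, means, var = _fit_once(X, k, family, rng, var_floor)
                if ll > ll_best:
                    ll_best, params_best = ll, (pi, means, var)
                if k == 1:
                    break  # deterministic
            bic = ll_best - 0.5 * _n_params(family, k, d) * np.log(n)
            if best is None or bic > best[0] + 1e-9:
                best = (bic, k, family, params_best)
            if bic > best_fam + 1e-9:
                best_fam = bic
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    bic, k, family, (pi, means, var) = best
    logR, _ = _estep(X, pi, means, var)
    labels = np.argmax(logR, axis=1)
    return labels, k, family, bic
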