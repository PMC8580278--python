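"""Shared regression kernels: vectorized OLS, IRLS logistic, CR1 sandwich.

These kernels back the per-site scans.  They are deliberately small and
deterministic; tests cross-check them against brute-force normal equations,
statsmodels maximum-likelihood fits, and cluster-bootstrap variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: smallest positive normal double; p-values that underflow are reported as
#: this value with a flag rather than as exact zero.
TINY_P = np.finfo(float).tiny


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise naming (nearly) collinear columns when the design is rank deficient."""
    n, p = X.shape
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    bad = d < max(n, p) * np.finfo(float).eps * (d.max() if d.size else 1.0)
    if bad.any():
        if names is None:
            names = [f"x{j}" for j in range(p)]
        cols = [names[j] for j in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")


@dataclass
class BatchOLS:
    """Vectorized OLS of many outcomes on one shared design."""

    coef: np.ndarray        # (p, m)
    se: np.ndarray          # (p, m)
    resid: np.ndarray       # (n, m)
    sigma2: np.ndarray      # (m,)
    df_resid: int
    xtx_inv: np.ndarray     # (p, p)


def batch_ols(X: np.ndarray, Y: np.ndarray, names: list[str] | None = None) -> BatchOLS:
    """OLS of each column of Y (n x m) on X (n x p) via a single QR factorization."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    check_full_rank(X, names)
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ coef
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return BatchOLS(coef=coef, se=se, resid=resid, sigma2=sigma2, df_resid=df, xtx_inv=xtx_inv)


def t_pvalues(coef: np.ndarray, se: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t-test p-values; underflowed p clipped to TINY_P with a flag."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    underflow = p < TINY_P
    p = np.where(underflow, TINY_P, p)
    return p, underflow


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    loglik: float


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    names: list[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least squares.

    Convergence is declared when the relative change in deviance falls below
    ``tol``.  Quasi-complete separation is flagged (diverging coefficients /
    vanishing information) instead of raising; the caller decides how to
    report the site.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    check_full_rank(X, names)

    beta = np.zeros(p)
    dev_old = np.inf
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        if np.abs(beta).max() > 1e3 or w.max() < 1e-10:
            separated = True
            break
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        with np.errstate(divide="ignore"):
            dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                                (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1)))
        if np.isfinite(dev_old) and abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = mu * (1.0 - mu)
    loglik = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    if separated or not converged:
        se = np.full(p, np.nan)
        if not separated:
            # non-convergence without divergence: report Wald SEs anyway
            try:
                se = np.sqrt(np.diag(np.linalg.inv(X.T @ (X * w[:, None]))))
            except np.linalg.LinAlgError:
                pass
    else:
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ (X * w[:, None]))))
    return LogisticFit(coef=beta, se=se, converged=converged, separated=separated,
                       n_iter=it, loglik=loglik)


def cluster_robust_cov(
    X: np.ndarray, resid: np.ndarray, clusters: np.ndarray, xtx_inv: np.ndarray
) -> np.ndarray:
    """CR1 sandwich covariance for pooled OLS with clustered observations.

    V = (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1, scaled by the CR1
    small-sample factor G/(G-1) * (N-1)/(N-K).
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    clusters = np.asarray(clusters)
    n, k = X.shape
    labels, inv = np.unique(clusters, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    p = X.shape[1]
    scores = np.zeros((g, p))
    np.add.at(scores, inv, X * resid[:, None])
    meat = scores.T @ scores
    c = (g / (g - 1.0)) * ((n - 1.0) / (n - k))
    return c * xtx_inv @ meat @ xtx_inv
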