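"""Repeated-measures confirmation of the smoking scan.

Both waves' methylation measurements are stacked into a panel (two rows per
individual) and regressed on the wave-1 smoking phenotype.  Point estimates
come from pooled OLS; inference uses a CR1 cluster-robust sandwich variance
by individual with t(G-1) reference distribution (LMRSE).  A random-intercept
linear mixed model fit by REML (profiling the intercept-variance ratio with a
bounded 1-D optimizer, tolerance 1e-8) serves as the computationally heavier
cross-check, and a change-on-change analysis regresses the wave-2 minus
wave-1 beta difference on the 3-level smoking-change variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._linalg import batch_ols, cluster_robust_cov, t_pvalues
from .containers import MethylationMatrix


def build_panel(
    meth_w1: MethylationMatrix,
    meth_w2: MethylationMatrix,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    sample_ids=None,
) -> dict:
    """Stack two waves into {Y (2n x sites), X columns, clusters, site_ids}.

    The exposure is the wave-1 smoking phenotype for both waves' rows; a wave
    indicator is included by default.  Only individuals present in both waves
    and with a defined exposure are kept.
    """
    if sample_ids is None:
        sample_ids = meth_w1.sample_ids.intersection(meth_w2.sample_ids)
    expo = exposure.loc[sample_ids]
    keep = expo.notna()
    sample_ids = pd.Index(sample_ids)[keep.to_numpy()]
    expo = expo.loc[sample_ids].to_numpy(dtype=float)

    y1 = meth_w1.beta.loc[:, sample_ids].to_numpy().T
    y2 = meth_w2.beta.loc[:, sample_ids].to_numpy().T
    Y = np.vstack([y1, y2])
    n = len(sample_ids)
    wave = np.concatenate([np.zeros(n), np.ones(n)])
    x_expo = np.concatenate([expo, expo])
    cols = [np.ones(2 * n), x_expo, wave]
    names = ["intercept", "exposure", "wave"]
    if covariates is not None:
        cv = covariates.loc[sample_ids].to_numpy(dtype=float)
        cols.append(np.vstack([cv, cv]))
        names += list(covariates.columns)
    X = np.column_stack(cols)
    clusters = np.concatenate([np.arange(n), np.arange(n)])
    return {"Y": Y, "X": X, "names": names, "clusters": clusters,
            "site_ids": meth_w1.site_ids, "sample_ids": sample_ids}


@dataclass
class RobustFit:
    """Single-site pooled OLS with CR1 cluster-robust covariance."""

    coef: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    df: int
    n_clusters: int
    names: list


def fit_lmrse(X: np.ndarray, y: np.ndarray, clusters, names=None) -> RobustFit:
    """Pooled OLS with CR1 cluster-robust SEs; p from t with G-1 df."""
    fit = batch_ols(np.asarray(X, float), np.asarray(y, float)[:, None], names)
    resid = fit.resid[:, 0]
    cov = cluster_robust_cov(X, resid, np.asarray(clusters), fit.xtx_inv)
    g = len(np.unique(clusters))
    se = np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(fit.coef[:, 0] / se), g - 1)
    return RobustFit(coef=fit.coef[:, 0], cov=cov, se=se, pvalues=p,
                     df=g - 1, n_clusters=g,
                     names=names or [f"x{j}" for j in range(X.shape[1])])


class ClusterRobustEWAS(BaseEstimator):
    """Vectorized LMRSE scan: one pooled regression per site, shared design.

    Attributes hold the exposure term only (the scan's quantity of interest);
    :func:`fit_lmrse` returns the full covariance for a single site.
    """

    def __init__(self, bonferroni_m: int | None = None, term: int = 1):
        self.bonferroni_m = bonferroni_m
        self.term = term

    def fit(self, X, Y, clusters, site_ids=None, names=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        clusters = np.asarray(clusters)
        n, k = X.shape
        labels, inv = np.unique(clusters, return_inverse=True)
        g = len(labels)
        if g < 2:
            raise ValueError("need at least 2 clusters")
        fit = batch_ols(X, Y, names)
        a = fit.xtx_inv[:, self.term]            # (X'X)^-1 column of the term
        w = X @ a                                 # n-vector, shared across sites
        scores = np.zeros((g, Y.shape[1]))
        np.add.at(scores, inv, w[:, None] * fit.resid)
        c = (g / (g - 1.0)) * ((n - 1.0) / (n - k))
        var = c * (scores**2).sum(axis=0)
        se = np.sqrt(var)
        coef = fit.coef[self.term]
        p = 2 * stats.t.sf(np.abs(coef / se), g - 1)
        self.coef_ = coef
        self.se_ = se
        self.pvalues_ = p
        self.n_clusters_ = g
        if site_ids is None:
            site_ids = pd.Index([f"site{j}" for j in range(Y.shape[1])])
        res = pd.DataFrame({"coef": coef, "se": se, "p": p}, index=site_ids)
        if self.bonferroni_m is not None:
            res["bonferroni"] = p * self.bonferroni_m < 0.05
        res["n_clusters"] = g
        self.results_ = res
        return self


def lmrse_scan(panel: dict, bonferroni_m: int | None = None) -> pd.DataFrame:
    est = ClusterRobustEWAS(bonferroni_m=bonferroni_m)
    est.fit(panel["X"], panel["Y"], panel["clusters"],
            site_ids=panel["site_ids"], names=panel["names"])
    return est.results_


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class MixedFit:
    coef: np.ndarray
    se: np.ndarray
    var_intercept: float
    var_resid: float
    lam: float          # variance ratio var_intercept / var_resid
    converged: bool
    names: list


class _ProfiledREML:
    """Precomputed pieces for profiling the random-intercept REML criterion.

    For V = I + lam * J (block per cluster), V^-1 = I - c_g J with
    c_g = lam / (1 + n_g lam); all cross-products reduce to cluster sums, so
    each candidate lam costs a p x p solve.
    """

    def __init__(self, X: np.ndarray, clusters: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        labels, inv = np.unique(np.asarray(clusters), return_inverse=True)
        self.inv = inv
        self.g = len(labels)
        self.n, self.p = self.X.shape
        self.ng = np.bincount(inv).astype(float)
        self.S = np.zeros((self.g, self.p))
        np.add.at(self.S, inv, self.X)
        self.xtx = self.X.T @ self.X

    def sums(self, y: np.ndarray):
        t = np.bincount(self.inv, weights=y, minlength=self.g)
        return self.X.T @ y, float(y @ y), t

    def neg_reml(self, lam: float, xty, yty, t):
        c = lam / (1.0 + self.ng * lam)
        A = self.xtx - (self.S * c[:, None]).T @ self.S
        b = xty - self.S.T @ (c * t)
        quad = yty - float(c @ t**2)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        rss = quad - float(b @ beta)
        df = self.n - self.p
        if rss <= 0:
            return np.inf, None, None
        sigma2 = rss / df
        logdet_v = float(np.log1p(self.ng * lam).sum())
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None
        crit = df * np.log(sigma2) + logdet_v + logdet_a
        return crit, beta, (sigma2, A)

    def fit(self, y: np.ndarray, tol: float = 1e-8) -> MixedFit:
        xty, yty, t = self.sums(np.asarray(y, dtype=float))

        def obj(log_lam):
            return self.neg_reml(np.exp(log_lam), xty, yty, t)[0]

        # bracket on log scale, include the boundary lam ~ 0
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 6.0), method="bounded",
                                       options={"xatol": tol})
        lam = float(np.exp(res.x))
        crit0 = self.neg_reml(1e-12, xty, yty, t)[0]
        if crit0 <= res.fun:
            lam = 0.0
        crit, beta, extra = self.neg_reml(max(lam, 1e-12), xty, yty, t)
        sigma2, A = extra
        cov = sigma2 * np.linalg.inv(A)
        return MixedFit(coef=beta, se=np.sqrt(np.diag(cov)),
                        var_intercept=lam * sigma2, var_resid=sigma2, lam=lam,
                        converged=bool(res.success) and np.isfinite(crit),
                        names=[f"x{j}" for j in range(self.p)])


def fit_lmem_random_intercept(X, y, clusters, tol: float = 1e-8) -> MixedFit:
    """REML random-intercept model via 1-D profiling of the variance ratio."""
    return _ProfiledREML(np.asarray(X, float), np.asarray(clusters)).fit(y, tol=tol)


class RandomInterceptEWAS(BaseEstimator):
    """Per-site random-intercept REML scan sharing the design across sites."""

    def __init__(self, term: int = 1, tol: float = 1e-8):
        self.term = term
        self.tol = tol

    def fit(self, X, Y, clusters, site_ids=None):
        Y = np.asarray(Y, dtype=float)
        prof = _ProfiledREML(np.asarray(X, float), clusters)
        m = Y.shape[1]
        coef = np.full(m, np.nan)
        se = np.full(m, np.nan)
        lam = np.full(m, np.nan)
        conv = np.zeros(m, dtype=bool)
        for j in range(m):
            fit = prof.fit(Y[:, j], tol=self.tol)
            conv[j] = fit.converged
            if fit.converged:
                coef[j] = fit.coef[self.term]
                se[j] = fit.se[self.term]
                lam[j] = fit.lam
        self.coef_ = coef
        self.se_ = se
        self.lam_ = lam
        self.converged_ = conv
        if site_ids is None:
            site_ids = pd.Index([f"site{j}" for j in range(m)])
        self.results_ = pd.DataFrame(
            {"coef": coef, "se": se, "var_ratio": lam, "converged": conv},
            index=site_ids)
        return self


def compare_estimates(coefs_a, coefs_b) -> float:
    """Pearson correlation between two aligned sets of per-site coefficients."""
    a = np.asarray(coefs_a, dtype=float)
    b = np.asarray(coefs_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two aligned coefficient vectors with >= 3 sites")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("coefficient vectors must have nonzero variance")
    return float(np.corrcoef(a, b)[0, 1])


def run_change_analysis(
    delta_beta, smoking_change, bonferroni_m: int = 76, covariates=None,
    site_ids=None,
) -> pd.DataFrame:
    """OLS of per-site beta change on the numeric 0/1/2 smoking-change variable.

    ``delta_beta`` is (sites x individuals); rows are wave-2 minus wave-1
    beta-values among controls.
    """
    D = np.asarray(delta_beta, dtype=float)
    change = np.asarray(smoking_change, dtype=float)
    if np.all(change == change[0]):
        raise ValueError("smoking-change variable is constant")
    n = len(change)
    cols = [np.ones(n), change]
    names = ["intercept", "change"]
    if covariates is not None:
        cv = np.asarray(covariates, dtype=float)
        cols.append(cv if cv.ndim == 2 else cv[:, None])
        names.append("cov")
    X = np.column_stack(cols)
    fit = batch_ols(X, D.T, names)
    p, _ = t_pvalues(fit.coef[1], fit.se[1], fit.df_resid)
    if site_ids is None:
        site_ids = pd.Index([f"site{j}" for j in range(D.shape[0])])
    return pd.DataFrame(
        {"coef": fit.coef[1], "se": fit.se[1], "p": p,
         "bonferroni": p * bonferroni_m < 0.05},
        index=site_ids)
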