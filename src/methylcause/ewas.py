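"""Per-site association scans with surrogate-variable adjustment.

Two scans are provided as scikit-learn-style estimators:

* :class:`LinearEWAS` — per-CpG ordinary least squares of methylation
  beta-values on the numeric 0-6 smoking phenotype, adjusting for sex, age,
  cell composition and k surrogate variables (default 12).  Significance is
  flagged at the epigenome-wide level 5e-8 and optionally after Bonferroni
  correction.
* :class:`LogisticEWAS` — per-CpG logistic regression of case status on the
  site's beta-value (coefficient reported per beta 0 -> 1) with the same
  covariate structure, optionally additionally adjusting for smoking.

Surrogate variables are estimated by residualizing every site on the model
terms, centering the residual matrix, and taking its top right singular
vectors (deterministic up to a sign fixed by convention).  This is the
SVD-based variant of surrogate variable analysis; the iteratively
re-weighted original is out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._linalg import TINY_P, batch_ols, irls_logistic, t_pvalues
from .containers import MethylationMatrix

GENOMEWIDE_ALPHA = 5e-8


def _as_beta_matrix(meth) -> tuple[np.ndarray, pd.Index, pd.DataFrame | None]:
    """Accept a MethylationMatrix or (sites x samples) DataFrame/array."""
    if isinstance(meth, MethylationMatrix):
        return meth.beta.to_numpy().T, meth.site_ids, meth.annotation
    if isinstance(meth, pd.DataFrame):
        return meth.to_numpy().T, meth.index, None
    arr = np.asarray(meth, dtype=float)
    return arr.T, pd.Index([f"site{j}" for j in range(arr.shape[0])]), None


def _covariate_array(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.atleast_2d(np.asarray(covariates, dtype=float))
    if arr.shape[0] != n:
        arr = arr.T
    return arr, [f"cov{j}" for j in range(arr.shape[1])]


class SurrogateVariableEstimator(BaseEstimator):
    """Residual-SVD surrogate variables for latent batch/technical structure.

    Parameters
    ----------
    n_components:
        Number of surrogate variables k (default 12).  Must satisfy
        k < n_samples - number of model terms.

    Attributes
    ----------
    surrogates_ : (n_samples, k) array with orthonormal columns.
    singular_values_ : singular values of the centered residual matrix.
    """

    def __init__(self, n_components: int = 12):
        self.n_components = n_components

    def fit(self, meth, exposure, covariates=None):
        Y, _, _ = _as_beta_matrix(meth)  # samples x sites
        n = Y.shape[0]
        exposure = np.asarray(exposure, dtype=float)
        cov, _ = _covariate_array(covariates, n)
        X = np.column_stack([np.ones(n), exposure, cov])
        k = self.n_components
        if k < 0 or k >= n - X.shape[1]:
            raise ValueError(
                f"n_components={k} must satisfy 0 <= k < n_samples - model terms "
                f"({n - X.shape[1]})"
            )
        if k == 0:
            self.surrogates_ = np.empty((n, 0))
            self.singular_values_ = np.empty(0)
            return self
        resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        resid = resid - resid.mean(axis=0, keepdims=True)
        # right singular vectors of the (sites x samples) residual matrix are
        # the left singular vectors of its transpose
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
        sv = U[:, :k]
        # sign convention: largest-|.| element of each column positive
        flip = np.sign(sv[np.abs(sv).argmax(axis=0), np.arange(k)])
        self.surrogates_ = sv * np.where(flip == 0, 1.0, flip)
        self.singular_values_ = s
        return self

    def fit_transform(self, meth, exposure, covariates=None) -> np.ndarray:
        return self.fit(meth, exposure, covariates).surrogates_


def estimate_surrogate_variables(meth, exposure, covariates=None, k: int = 12) -> np.ndarray:
    return SurrogateVariableEstimator(n_components=k).fit_transform(meth, exposure, covariates)


def apply_thresholds(
    pvalues, genomewide_alpha: float = GENOMEWIDE_ALPHA, bonferroni_m: int | None = None
) -> pd.DataFrame:
    """Genome-wide (p < alpha) and Bonferroni (p * m < 0.05) significance flags."""
    p = np.asarray(pvalues, dtype=float)
    out = pd.DataFrame({"genomewide": p < genomewide_alpha})
    if bonferroni_m is not None:
        if bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")
        out["bonferroni"] = p * bonferroni_m < 0.05
    return out


def _results_frame(site_ids, annotation, coef, se, p, underflow,
                   genomewide_alpha, bonferroni_m) -> pd.DataFrame:
    res = pd.DataFrame({"coef": coef, "se": se, "p": p, "p_underflow": underflow},
                       index=site_ids)
    if annotation is not None:
        for c in ("chr", "pos", "gene"):
            if c in annotation.columns:
                res.insert(0, c, annotation[c])
    flags = apply_thresholds(p, genomewide_alpha, bonferroni_m)
    flags.index = res.index
    return pd.concat([res, flags], axis=1)


class LinearEWAS(BaseEstimator):
    """Per-site OLS of beta-values on a numeric exposure with covariates + SVs.

    Parameters
    ----------
    n_svs:
        Number of surrogate variables estimated from the data and added to the
        model (default 12).  Set 0 to skip SV adjustment.
    genomewide_alpha, bonferroni_m:
        Significance thresholds applied to the per-site p-values.

    Attributes
    ----------
    coef_, se_, pvalues_ : per-site exposure coefficient (beta units per
        exposure level), standard error and two-sided t-test p-value.
    results_ : tidy per-site DataFrame with annotation and flags.
    surrogates_ : estimated surrogate-variable matrix.
    """

    def __init__(self, n_svs: int = 12, genomewide_alpha: float = GENOMEWIDE_ALPHA,
                 bonferroni_m: int | None = None):
        self.n_svs = n_svs
        self.genomewide_alpha = genomewide_alpha
        self.bonferroni_m = bonferroni_m

    def fit(self, meth, exposure, covariates=None, surrogates=None):
        Y, site_ids, annotation = _as_beta_matrix(meth)
        n = Y.shape[0]
        exposure = np.asarray(exposure, dtype=float)
        if len(exposure) != n:
            raise ValueError("exposure length must match number of samples")
        cov, cov_names = _covariate_array(covariates, n)
        if surrogates is None and self.n_svs > 0:
            surrogates = estimate_surrogate_variables(meth, exposure, cov, k=self.n_svs)
        elif surrogates is None:
            surrogates = np.empty((n, 0))
        X = np.column_stack([np.ones(n), exposure, cov, surrogates])
        names = (["intercept", "exposure"] + cov_names
                 + [f"sv{j+1}" for j in range(surrogates.shape[1])])
        if n - X.shape[1] < 10:
            raise ValueError("fewer than 10 residual degrees of freedom")
        fit = batch_ols(X, Y, names)
        p, underflow = t_pvalues(fit.coef[1], fit.se[1], fit.df_resid)
        self.surrogates_ = surrogates
        self.design_columns_ = names
        self.coef_ = fit.coef[1]
        self.se_ = fit.se[1]
        self.pvalues_ = p
        self.df_resid_ = fit.df_resid
        self.results_ = _results_frame(site_ids, annotation, fit.coef[1], fit.se[1],
                                       p, underflow, self.genomewide_alpha,
                                       self.bonferroni_m)
        return self

    def significant_sites(self) -> pd.Index:
        return self.results_.index[self.results_["genomewide"]]


def run_linear_ewas(meth, exposure, covariates=None, svs=None, *, n_svs: int = 12,
                    genomewide_alpha: float = GENOMEWIDE_ALPHA,
                    bonferroni_m: int | None = None) -> pd.DataFrame:
    est = LinearEWAS(n_svs=n_svs, genomewide_alpha=genomewide_alpha,
                     bonferroni_m=bonferroni_m)
    return est.fit(meth, exposure, covariates, surrogates=svs).results_


def or_per_percent(coef) -> np.ndarray | float:
    """Odds ratio per 1% methylation increase from a log-odds-per-unit coefficient.

    The logistic scan reports log-odds per beta-value 0 -> 1; a 1% increase is
    one-hundredth of that unit, so OR = exp(coef / 100).
    """
    coef = np.asarray(coef, dtype=float)
    out = np.exp(coef / 100.0)
    return float(out) if out.ndim == 0 else out


class LogisticEWAS(BaseEstimator):
    """Per-site logistic regression of case status on methylation.

    The per-site model is case ~ beta + covariates (+ SVs) (+ smoking when
    ``adjust_smoking``).  Coefficients are log-odds per beta 0 -> 1; the
    results table also reports the odds ratio per 1% methylation increase.
    Sites with (quasi-)complete separation are reported with missing
    estimates and flagged, never raised.
    """

    def __init__(self, adjust_smoking: bool = False, n_svs: int = 0,
                 genomewide_alpha: float = GENOMEWIDE_ALPHA,
                 bonferroni_m: int | None = None, tol: float = 1e-10):
        self.adjust_smoking = adjust_smoking
        self.n_svs = n_svs
        self.genomewide_alpha = genomewide_alpha
        self.bonferroni_m = bonferroni_m
        self.tol = tol

    def fit(self, meth, case_status, covariates=None, smoking=None, surrogates=None):
        from scipy import stats as sstats

        Y, site_ids, annotation = _as_beta_matrix(meth)
        n, m = Y.shape
        y = np.asarray(case_status, dtype=float)
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")
        cov, _ = _covariate_array(covariates, n)
        if self.adjust_smoking:
            if smoking is None:
                raise ValueError("adjust_smoking=True requires the smoking phenotype")
            cov = np.column_stack([cov, np.asarray(smoking, dtype=float)])
        if surrogates is None:
            if self.n_svs > 0:
                surrogates = estimate_surrogate_variables(meth, y, cov, k=self.n_svs)
            else:
                surrogates = np.empty((n, 0))
        coef = np.full(m, np.nan)
        se = np.full(m, np.nan)
        sep = np.zeros(m, dtype=bool)
        for j in range(m):
            X = np.column_stack([np.ones(n), Y[:, j], cov, surrogates])
            fit = irls_logistic(X, y, tol=self.tol)
            if fit.separated or not np.isfinite(fit.se[1]):
                sep[j] = True
                continue
            coef[j] = fit.coef[1]
            se[j] = fit.se[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = coef / se
        p = 2 * sstats.norm.sf(np.abs(z))
        underflow = np.zeros(m, dtype=bool)
        ok = np.isfinite(p)
        underflow[ok] = p[ok] < TINY_P
        p[ok & (p < TINY_P)] = TINY_P
        self.coef_ = coef
        self.se_ = se
        self.pvalues_ = p
        self.separated_ = sep
        res = _results_frame(site_ids, annotation, coef, se, p, underflow,
                             self.genomewide_alpha, self.bonferroni_m)
        res["or_per_percent"] = np.round(or_per_percent(coef), 2)
        res["separated"] = sep
        res.loc[sep, ["genomewide"]] = False
        self.results_ = res
        return self

    def significant_sites(self) -> pd.Index:
        return self.results_.index[self.results_["genomewide"].fillna(False)]


def run_logistic_ewas(case_status, meth, covariates=None, svs=None, *,
                      adjust_smoking: bool = False, smoking=None, n_svs: int = 0,
                      genomewide_alpha: float = GENOMEWIDE_ALPHA,
                      bonferroni_m: int | None = None) -> pd.DataFrame:
    est = LogisticEWAS(adjust_smoking=adjust_smoking, n_svs=n_svs,
                       genomewide_alpha=genomewide_alpha, bonferroni_m=bonferroni_m)
    return est.fit(meth, case_status, covariates, smoking=smoking,
                   surrogates=svs).results_
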