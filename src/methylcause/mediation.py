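"""Counterfactual mediation of the smoking -> lung-cancer effect by methylation.

For a continuous mediator M and binary outcome Y the default product-method
estimator fits

    M = b0 + b1 * A + covariates                       (linear)
    logit P(Y=1) = t0 + tA * A + tM * M + covariates   (logistic)

and, with no exposure-mediator interaction and an exposure contrast
(a, a*) (default one level of the smoking phenotype):

    log NIE = tM * b1 * (a - a*)       natural indirect effect
    log NDE = tA * (a - a*)            natural direct effect
    log TE  = NDE + NIE                total effect (exact decomposition)

The relative indirect effect is NIE / TE on the log-odds scale.  Percentile
confidence intervals come from a nonparametric bootstrap that resamples
individuals and refits both models jointly.  The product formula treats the
outcome as rare; a Monte-Carlo counterfactual-simulation estimator
(``estimator="simulation"``) is provided as the cross-check and for
non-rare outcomes.

A screen over candidate sites (the intersection of smoking-EWAS and
cancer-EWAS hits) calls a site "identified" when its NIE bootstrap CI
excludes zero, then combines identified sites into a weighted methylation
score (beta-values weighted by their lung-cancer logistic effect sizes) and
analyzes the score as a single mediator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator

from ._linalg import batch_ols, irls_logistic


def relative_indirect(total: float, indirect: float, tol: float = 1e-12) -> float:
    """Indirect effect divided by total effect; NaN when the total is ~0."""
    if abs(total) <= tol:
        return float("nan")
    return indirect / total


def weighted_methylation_score(beta: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Per-individual sum of site beta-values weighted by outcome effect sizes.

    ``beta`` is (sites x individuals); ``weights`` is indexed by site id.
    Raises when a weighted site is absent from the matrix.
    """
    missing = [s for s in weights.index if s not in beta.index]
    if missing:
        raise KeyError(f"sites absent from the methylation matrix: {missing}")
    sub = beta.loc[weights.index]
    return pd.Series(weights.to_numpy() @ sub.to_numpy(), index=beta.columns,
                     name="methylation_score")


def fit_mediator_model(exposure, mediator, covariates=None):
    """OLS of the mediator on exposure (+ covariates); returns (coefs, se, names)."""
    a = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    n = len(a)
    cols = [np.ones(n), a]
    names = ["intercept", "exposure"]
    if covariates is not None:
        cv = np.asarray(covariates, dtype=float)
        cols.append(cv if cv.ndim == 2 else cv[:, None])
        names += [f"cov{j}" for j in range(cols[-1].shape[1])]
    X = np.column_stack(cols)
    fit = batch_ols(X, m[:, None], names)
    return fit.coef[:, 0], fit.se[:, 0], names


@dataclass
class MediationResult:
    total: float
    direct: float
    indirect: float
    relative: float
    ci_total: tuple
    ci_direct: tuple
    ci_indirect: tuple
    ci_relative: tuple
    mediator_coef: float
    n_boot: int
    identified: bool


class MediationAnalysis(BaseEstimator):
    """Counterfactual natural-effects decomposition for one mediator.

    Parameters
    ----------
    contrast:
        Exposure contrast (a, a*); default (1, 0), i.e. per exposure level.
    n_boot:
        Bootstrap replicates for percentile CIs (default 1000; >= 100).
    ci_level:
        CI coverage (default 0.95).
    estimator:
        "product" (default; rare-outcome product formula, exact
        NDE + NIE = TE decomposition) or "simulation" (Monte-Carlo
        counterfactual simulation of the mediator).
    random_state:
        Seed for the bootstrap and the Monte-Carlo draws.
    """

    def __init__(self, contrast=(1.0, 0.0), n_boot: int = 1000,
                 ci_level: float = 0.95, estimator: str = "product",
                 n_mc: int = 2000, random_state: int | None = 0):
        self.contrast = contrast
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.estimator = estimator
        self.n_mc = n_mc
        self.random_state = random_state

    def _effects(self, a, m, y, cov, rng) -> tuple[float, float, float]:
        n = len(a)
        c1, c0 = self.contrast
        cols = [np.ones(n), a]
        if cov is not None:
            cols.append(cov)
        Xm = np.column_stack(cols)
        bm = np.linalg.lstsq(Xm, m, rcond=None)[0]
        cols_y = [np.ones(n), a, m]
        if cov is not None:
            cols_y.append(cov)
        Xy = np.column_stack(cols_y)
        fit = irls_logistic(Xy, y)
        tA, tM = fit.coef[1], fit.coef[2]
        if self.estimator == "product":
            nie = tM * bm[1] * (c1 - c0)
            nde = tA * (c1 - c0)
            return nde + nie, nde, nie
        # counterfactual simulation: draw M(a) from the fitted mediator model
        resid_sd = float(np.std(m - Xm @ bm, ddof=Xm.shape[1]))
        base = np.tile(np.arange(n), self.n_mc)
        eps = rng.normal(0.0, resid_sd, size=len(base))
        covt = cov[base] if cov is not None else None

        def mean_p(a_set, m_at):
            mu_m = bm[0] + bm[1] * m_at
            if cov is not None:
                mu_m = mu_m + covt @ bm[2:]
            m_draw = mu_m + eps
            lp = fit.coef[0] + tA * a_set + tM * m_draw
            if cov is not None:
                lp = lp + covt @ fit.coef[3:]
            return float(special.expit(lp).mean())

        p11 = mean_p(c1, c1)   # Y(a, M(a))
        p10 = mean_p(c1, c0)   # Y(a, M(a*))
        p00 = mean_p(c0, c0)   # Y(a*, M(a*))
        logodds = lambda p: np.log(p / (1 - p))
        te = logodds(p11) - logodds(p00)
        nde = logodds(p10) - logodds(p00)
        return te, nde, te - nde

    def fit(self, exposure, mediator, outcome, covariates=None):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        c1, c0 = self.contrast
        if c1 == c0:
            raise ValueError("exposure contrast endpoints must differ")
        a = np.asarray(exposure, dtype=float)
        m = np.asarray(mediator, dtype=float)
        y = np.asarray(outcome, dtype=float)
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
        rng = np.random.default_rng(self.random_state)
        te, nde, nie = self._effects(a, m, y, cov, rng)

        n = len(a)
        boots = np.empty((self.n_boot, 3))
        for b in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():
                boots[b] = np.nan
                continue
            try:
                boots[b] = self._effects(a[idx], m[idx], yb,
                                         cov[idx] if cov is not None else None, rng)
            except (ValueError, np.linalg.LinAlgError):
                boots[b] = np.nan
        alpha = 1.0 - self.ci_level
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        ok = ~np.isnan(boots).any(axis=1)
        bt = boots[ok]
        ci_te = tuple(np.percentile(bt[:, 0], qs))
        ci_nde = tuple(np.percentile(bt[:, 1], qs))
        ci_nie = tuple(np.percentile(bt[:, 2], qs))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_b = bt[:, 2] / bt[:, 0]
        ci_rel = tuple(np.nanpercentile(rel_b, qs))

        bm_coef, _, _ = fit_mediator_model(a, m, cov)
        self.result_ = MediationResult(
            total=te, direct=nde, indirect=nie,
            relative=relative_indirect(te, nie),
            ci_total=ci_te, ci_direct=ci_nde, ci_indirect=ci_nie,
            ci_relative=ci_rel, mediator_coef=bm_coef[1],
            n_boot=int(ok.sum()),
            identified=bool(ci_nie[0] > 0 or ci_nie[1] < 0),
        )
        self.total_ = te
        self.direct_ = nde
        self.indirect_ = nie
        self.relative_ = self.result_.relative
        return self


def estimate_natural_effects(exposure, mediator, outcome, covariates=None,
                             **kwargs) -> MediationResult:
    est = MediationAnalysis(**kwargs)
    return est.fit(exposure, mediator, outcome, covariates).result_


def run_mediation_screen(
    beta: pd.DataFrame,
    candidate_sites,
    weights: pd.Series,
    exposure,
    outcome,
    covariates=None,
    n_boot: int = 1000,
    random_state: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, MediationResult | None]:
    """Per-site mediation over the candidate set, then the weighted-score model.

    ``weights`` are the per-site lung-cancer logistic coefficients from the
    smoking-unadjusted scan; only identified sites (NIE CI excluding zero)
    enter the score.  Returns (per-site table, score-level result or None
    when nothing is identified).  An empty candidate set yields an empty
    table with a warning.
    """
    import warnings as _warnings

    candidate_sites = list(candidate_sites)
    rows = []
    if not candidate_sites:
        _warnings.warn("empty candidate mediator set", stacklevel=2)
    for k, site in enumerate(candidate_sites):
        res = estimate_natural_effects(
            exposure, beta.loc[site].to_numpy(), outcome, covariates,
            n_boot=n_boot, random_state=random_state + k, **kwargs)
        rows.append({
            "site_id": site, "total": res.total, "indirect": res.indirect,
            "indirect_lo": res.ci_indirect[0], "indirect_hi": res.ci_indirect[1],
            "relative": res.relative, "relative_lo": res.ci_relative[0],
            "relative_hi": res.ci_relative[1], "identified": res.identified,
        })
    table = pd.DataFrame(rows).set_index("site_id") if rows else pd.DataFrame(
        columns=["total", "indirect", "indirect_lo", "indirect_hi",
                 "relative", "relative_lo", "relative_hi", "identified"])
    score_result = None
    identified = list(table.index[table["identified"]]) if len(table) else []
    if identified:
        score = weighted_methylation_score(beta, weights.loc[identified])
        score_result = estimate_natural_effects(
            exposure, score.to_numpy(), outcome, covariates,
            n_boot=n_boot, random_state=random_state + len(candidate_sites),
            **kwargs)
    return table, score_result
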