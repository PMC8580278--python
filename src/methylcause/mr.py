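"""Two-step Mendelian randomization.

Step one (one-sample): an unweighted allele-count score over the three
smoking-associated SNPs instruments the smoking phenotype in a two-stage
least squares (2SLS) regression of methylation M-values on smoking, with
instrument-strength diagnostics (R^2, F).  The instrument is deliberately
weak in the emulated design (the score explains ~1.8% of smoking variance).

Step two (two-sample): summary-statistic MR of lung cancer on methylation
using per-CpG mQTL instruments — the Wald ratio for a single instrument,
fixed-effect inverse-variance weighting (IVW) for several — with allele
harmonization, an inclusive 1 Mb cis filter, and Bonferroni flags over the
screened sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._linalg import batch_ols

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000
PALINDROMIC = {frozenset("AT"), frozenset("CG")}


@dataclass
class MrResult:
    method: str                  # "wald", "ivw" or "tsls"
    estimate: float
    se: float
    p: float
    n_instruments: int
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method == "wald" and self.n_instruments != 1:
            raise ValueError("Wald ratio uses exactly one instrument")


def _with_or(method, est, se, n_instruments, **extras) -> MrResult:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * stats.norm.sf(abs(z))
    lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
    return MrResult(method=method, estimate=est, se=se, p=p,
                    n_instruments=n_instruments, odds_ratio=float(np.exp(est)),
                    ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
                    extras=extras)


# ---------------------------------------------------------------------------
# first step: one-sample MR


def build_genetic_score(genotypes: pd.DataFrame, snps=None, weights=None) -> pd.Series:
    """Weighted allele-count score; default unit weights over all columns."""
    if snps is not None:
        missing = [s for s in snps if s not in genotypes.columns]
        if missing:
            raise KeyError(f"SNPs absent from the genotype table: {missing}")
        genotypes = genotypes[list(snps)]
    w = np.ones(genotypes.shape[1]) if weights is None else np.asarray(weights, float)
    if len(w) != genotypes.shape[1]:
        raise ValueError("need one weight per SNP")
    g = genotypes.to_numpy(dtype=float)
    keep = ~np.isnan(g).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d individuals with missing genotypes", dropped)
    return pd.Series(g[keep] @ w, index=genotypes.index[keep], name="genetic_score")


def instrument_strength(score, exposure) -> tuple[float, float]:
    """(R^2, F) from OLS of the exposure on the score; F = R2/(1-R2)*(n-2)."""
    s = np.asarray(score, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if len(s) <= 2:
        raise ValueError("need n > 2")
    if s.std() == 0:
        raise ValueError("instrument score is constant")
    r = np.corrcoef(s, e)[0, 1]
    r2 = r * r
    if r2 >= 1.0:
        return 1.0, float("inf")
    f = (r2 / (1 - r2)) * (len(s) - 2)
    return float(r2), float(f)


class TwoStageLeastSquares(BaseEstimator):
    """One-sample MR by 2SLS with a single instrument score.

    Stage 1 regresses the exposure on the score (+ covariates); stage 2
    regresses the outcome (here a methylation M-value) on the fitted
    exposure (+ covariates).  The reported SE uses residuals recomputed with
    the observed exposure (standard 2SLS variance).  A first-stage F below
    ``weak_f_threshold`` flags the result weak-instrument but it is still
    reported.
    """

    def __init__(self, weak_f_threshold: float = 10.0):
        self.weak_f_threshold = weak_f_threshold

    def fit(self, score, exposure, outcome, covariates=None):
        s = np.asarray(score, dtype=float)
        a = np.asarray(exposure, dtype=float)
        y = np.asarray(outcome, dtype=float)
        n = len(s)
        if s.std() == 0 or a.std() == 0:
            raise ValueError("instrument and exposure must be nonconstant")
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
        Z = np.column_stack([np.ones(n), s] + ([cov] if cov is not None else []))
        b1 = np.linalg.lstsq(Z, a, rcond=None)[0]
        a_hat = Z @ b1
        X2 = np.column_stack([np.ones(n), a_hat] + ([cov] if cov is not None else []))
        fit2 = batch_ols(X2, y[:, None])
        b2 = fit2.coef[:, 0]
        # 2SLS variance: residuals with the observed exposure
        Xobs = np.column_stack([np.ones(n), a] + ([cov] if cov is not None else []))
        resid = y - Xobs @ b2
        sigma2 = float(resid @ resid) / (n - X2.shape[1])
        cov_b = sigma2 * fit2.xtx_inv
        se = float(np.sqrt(cov_b[1, 1]))
        r2, f = instrument_strength(s, a)
        est = float(b2[1])
        res = _with_or("tsls", est, se, 1, first_stage=b1,
                       variance_explained=r2, F=f,
                       weak_instrument=f < self.weak_f_threshold)
        res.odds_ratio = res.ci_low = res.ci_high = None  # linear outcome scale
        self.estimate_ = est
        self.se_ = se
        self.f_statistic_ = f
        self.r2_ = r2
        self.weak_instrument_ = f < self.weak_f_threshold
        self.result_ = res
        return self


def two_stage_least_squares(score, exposure, outcome, covariates=None) -> MrResult:
    return TwoStageLeastSquares().fit(score, exposure, outcome, covariates).result_


# ---------------------------------------------------------------------------
# second step: two-sample summary MR


def wald_ratio(gamma: float, Gamma: float, se_Gamma: float) -> MrResult:
    """Single-instrument causal estimate Gamma/gamma, first-order SE."""
    if gamma == 0:
        raise ValueError("instrument-exposure effect gamma must be nonzero")
    if se_Gamma <= 0:
        raise ValueError("se_Gamma must be positive")
    est = Gamma / gamma
    se = se_Gamma / abs(gamma)
    return _with_or("wald", float(est), float(se), 1)


def ivw(gammas, Gammas, se_Gammas) -> MrResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    Equivalent to weighted least squares of Gamma on gamma through the
    origin with weights 1/se_Gamma^2.
    """
    g = np.asarray(gammas, dtype=float)
    G = np.asarray(Gammas, dtype=float)
    s = np.asarray(se_Gammas, dtype=float)
    if not (len(g) == len(G) == len(s)):
        raise ValueError("instrument and outcome vectors must align")
    if len(g) < 1:
        raise ValueError("need at least one instrument")
    if np.any(s <= 0):
        raise ValueError("all se_Gamma must be positive")
    if len(g) == 1:
        return wald_ratio(float(g[0]), float(G[0]), float(s[0]))
    w = g**2 / s**2
    est = float(np.sum(g * G / s**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return _with_or("ivw" if len(g) > 1 else "wald", est, se, len(g))


def harmonize(instruments: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf_margin: float = 0.08) -> pd.DataFrame:
    """Align outcome effect alleles to the instrument's effect allele.

    Straight matches pass through; swapped alleles flip the outcome sign;
    palindromic SNPs are resolved by allele frequency when the instrument
    EAF is far from 0.5 (|eaf-0.5| > margin) and dropped otherwise;
    unmatched SNPs raise with the offending ids.
    """
    merged = instruments.merge(outcome, on="snp", suffixes=("", "_out"))
    missing = set(instruments["snp"]) - set(merged["snp"])
    if missing:
        raise KeyError(f"no outcome statistics for SNPs: {sorted(missing)}")
    rows = []
    for r in merged.itertuples(index=False):
        ea, oa = r.effect_allele, r.other_allele
        ea_o, oa_o = r.effect_allele_out, r.other_allele_out
        pal = frozenset((ea, oa)) in PALINDROMIC
        beta_out = r.beta_out if hasattr(r, "beta_out") else r.beta
        if pal:
            if abs(r.eaf - 0.5) <= palindromic_eaf_margin:
                logger.warning("dropping palindromic SNP %s (eaf %.2f ~ 0.5)",
                               r.snp, r.eaf)
                continue
            # strand-ambiguous: keep orientation as reported
            rows.append((r.snp, r.beta, r.se, beta_out, r.se_out))
            continue
        if (ea_o, oa_o) == (ea, oa):
            rows.append((r.snp, r.beta, r.se, beta_out, r.se_out))
        elif (ea_o, oa_o) == (oa, ea):
            rows.append((r.snp, r.beta, r.se, -beta_out, r.se_out))
        else:
            raise ValueError(f"allele mismatch for {r.snp}: "
                             f"{ea}/{oa} vs {ea_o}/{oa_o}")
    return pd.DataFrame(rows, columns=["snp", "gamma", "se_gamma",
                                       "Gamma", "se_Gamma"])


def filter_cis(instruments: pd.DataFrame, cpg_chr, cpg_pos,
               window: int = CIS_WINDOW) -> pd.DataFrame:
    """Keep instruments on the CpG's chromosome within the window (inclusive)."""
    same = instruments["chr"].astype(str) == str(cpg_chr)
    near = (instruments["pos"] - int(cpg_pos)).abs() <= window
    out = instruments[same & near]
    if out.empty:
        logger.warning("no cis instruments within %d bp of %s:%s",
                       window, cpg_chr, cpg_pos)
    return out


def variance_explained_summary(eaf, gamma, var_m: float = 1.0) -> float:
    """Share of mediator variance explained by instruments: sum 2f(1-f)g^2 / var."""
    f = np.asarray(eaf, dtype=float)
    g = np.asarray(gamma, dtype=float)
    return float(np.sum(2 * f * (1 - f) * g**2) / var_m)


def mr_second_step_screen(
    instruments: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    bonferroni_m: int | None = None,
    cis_only: bool = False,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Per-CpG Wald/IVW screen over the mQTL instrument table.

    ``instruments`` follows the mQTL summary schema (snp, chr, pos,
    effect_allele, other_allele, eaf, beta, se, p, cpg_id, cpg_chr, cpg_pos).
    Sites whose instruments all lack outcome statistics (or fail
    harmonization) are reported as untestable rather than dropped.
    """
    m = bonferroni_m if bonferroni_m is not None else instruments["cpg_id"].nunique()
    rows = []
    for cpg, tab in instruments.groupby("cpg_id", sort=True):
        if cis_only:
            tab = filter_cis(tab, tab["cpg_chr"].iloc[0], tab["cpg_pos"].iloc[0],
                             window)
        status = "ok"
        res = None
        tab = tab[tab["snp"].isin(outcome_stats["snp"])]
        if tab.empty:
            status = "untestable"
        else:
            harm = harmonize(tab, outcome_stats)
            if harm.empty:
                status = "untestable"
            else:
                res = ivw(harm["gamma"], harm["Gamma"], harm["se_Gamma"])
        rows.append({
            "cpg_id": cpg,
            "status": status,
            "method": res.method if res else None,
            "n_instruments": res.n_instruments if res else 0,
            "estimate": res.estimate if res else np.nan,
            "se": res.se if res else np.nan,
            "odds_ratio": res.odds_ratio if res else np.nan,
            "ci_low": res.ci_low if res else np.nan,
            "ci_high": res.ci_high if res else np.nan,
            "p": res.p if res else np.nan,
            "variance_explained": variance_explained_summary(
                tab["eaf"], tab["beta"]) if not tab.empty else np.nan,
            "bonferroni": (res.p * m < 0.05) if res else False,
        })
    return pd.DataFrame(rows).set_index("cpg_id")
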