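"""Synthetic nested case-control cohorts with a fully known causal structure.

The generator emulates a two-wave population health survey from which a
nested case-control study is drawn: genotypes at three smoking-associated
SNPs plus per-site methylation QTLs, a smoking liability that the genetic
score explains a small configurable share of (default 1.8%), the 7-level
smoking phenotype, blood methylation at hundreds to thousands of CpG sites
measured at two waves about 11 years apart, leukocyte composition and batch
structure, and a binary lung-cancer outcome with configurable direct
(smoking -> cancer) and mediated (smoking -> methylation -> cancer) effects.
Each sampled case is paired with an age- and sex-matched control.

Methylation is generated linearly on the M-value (base-2 logit) scale, where
planted per-level smoking effects, mQTL allele effects, cell-composition and
batch terms are all additive, then stored as beta-values in (0,1).  The
default mediated effect is zero: downstream mediation and second-step MR
stages are then operating under a true null, which is the regime the
pipeline's error-control tests exercise.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import phenotypes as ph
from .containers import MethylationMatrix

logger = logging.getLogger(__name__)

SMOKING_SNPS = ("rs6265", "rs1051730", "rs3025343")
#: index (within the smoking SNPs) of the quantity-associated variant
QUANTITY_SNP = 1

# Wave-to-wave smoking status transition rows (never, former, current), taken
# from the observed marginals of a 128-control roster: never 59/63 stay,
# 3/63 -> former, 1/63 -> current; former 29/35 stay, 6/35 resume; current
# 16/30 quit, 14/30 continue.
DEFAULT_TRANSITIONS = np.array(
    [
        [59 / 63, 3 / 63, 1 / 63],
        [0.0, 29 / 35, 6 / 35],
        [0.0, 16 / 30, 14 / 30],
    ]
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_individuals: int = 2000
    n_sites: int = 1000
    n_signal_sites: int = 76
    n_mediator_sites: int = 14
    n_smoking_snps: int = 3
    allele_freqs: tuple = (0.20, 0.35, 0.08)
    score_weights: tuple = (1.0, 1.0, 1.0)
    score_r2: float = 0.018
    status_probs: tuple = (0.50, 0.25, 0.25)
    mqtls_per_site: tuple = (1, 9)
    mqtl_freq_range: tuple = (0.05, 0.50)
    mqtl_effect_sd: float = 0.30
    cis_fraction: float = 0.5
    tau_scale: float = 0.25
    frac_hypo: float = 0.83
    theta_direct: float = 0.5
    theta_med: float = 0.0
    n_cell_types: int = 6
    cell_concentration: float = 10.0
    cell_effect_sd: float = 0.5
    n_batches: int = 4
    batch_effect_sd: float = 0.3
    person_sd: float = 0.3
    residual_sd: float = 0.35
    wave_years: float = 11.0
    wave_transition_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    case_fraction: float = 0.07
    n_cases: int = 140
    age_mean: float = 56.0
    age_sd: float = 8.0
    age_caliper: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_sites <= 0:
            raise ValueError("n_individuals and n_sites must be positive")
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(freqs) != self.n_smoking_snps:
            raise ValueError("allele_freqs length must equal n_smoking_snps")
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        for name in ("mqtl_effect_sd", "cell_effect_sd", "batch_effect_sd",
                     "person_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        validate_transition_matrix(np.asarray(self.wave_transition_probs, dtype=float))
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 <= self.score_r2 < 1:
            raise ValueError("score_r2 must lie in [0, 1)")
        if self.n_signal_sites > self.n_sites:
            raise ValueError("n_signal_sites cannot exceed n_sites")
        if self.n_mediator_sites > self.n_signal_sites:
            raise ValueError("n_mediator_sites cannot exceed n_signal_sites")


def validate_transition_matrix(t: np.ndarray) -> None:
    if t.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3 (never, former, current)")
    if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition rows must be nonnegative and sum to 1")
    if t[1, 0] != 0 or t[2, 0] != 0:
        raise ValueError("transitions back to never are impossible "
                         "(pack-years never decrease)")


@dataclass
class CohortTruth:
    """Planted parameters of a simulated cohort, for recovery tests."""

    site_ids: pd.Index
    mu0: np.ndarray
    tau: np.ndarray                    # M-value per smoking level, per site
    theta_direct: float
    theta_med: float
    mediator_sites: list
    cell_coefs: np.ndarray             # (n_sites, n_cell_types - 1)
    batch_offsets: np.ndarray          # (n_sites, n_batches)
    mqtls: pd.DataFrame                # snp, site_id, chr, pos, eaf, gamma, effect_allele, other_allele
    annotation: pd.DataFrame


@dataclass
class Cohort:
    """Simulated two-wave cohort plus its nested case-control sample."""

    pheno: pd.DataFrame
    genotypes: pd.DataFrame
    meth_w1: MethylationMatrix
    meth_w2: MethylationMatrix
    cells_w1: pd.DataFrame
    cells_w2: pd.DataFrame
    batch_w1: np.ndarray
    batch_w2: np.ndarray
    mqtl_dosages: pd.DataFrame
    matched: pd.DataFrame

    def nested_ids(self) -> pd.Index:
        """Sample ids of the nested case-control subset (cases + matched controls)."""
        return self.pheno.index[self.pheno["matchset"].notna()]


# ---------------------------------------------------------------------------
# genotypes and smoking


def simulate_genotypes(freqs, n: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotypes: dosage = sum of two Bernoulli(f) draws."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)


def simulate_smoking(
    genotypes: np.ndarray,
    score_weights,
    rng: np.random.Generator,
    *,
    thresholds: tuple | None = None,
    status_probs=(0.50, 0.25, 0.25),
    score_r2: float = 0.018,
    quantity_snp: int = QUANTITY_SNP,
    quantity_effect: float = 0.15,
    packyear_means=(12.0, 18.0),
    packyear_shape: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoking status and pack-years from a genetic liability model.

    Liability = s * standardized genetic score + standard normal noise, cut
    into never/former/current; pack-years are Gamma with status-dependent
    mean that also rises with the quantity-SNP dosage.  The scale ``s`` is
    calibrated by a deterministic fixed point so that the 7-level phenotype
    regressed on the raw score attains R^2 ~= ``score_r2`` (ordinal
    coarsening attenuates the liability R^2, so the calibration targets the
    phenotype directly).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    n, n_snps = genotypes.shape
    w = np.asarray(score_weights, dtype=float)
    if len(w) != n_snps:
        raise ValueError("need one score weight per SNP")
    if thresholds is not None:
        t = np.asarray(thresholds, dtype=float)
        if t.ndim != 1 or len(t) != 2 or not t[0] < t[1]:
            raise ValueError("thresholds must be two strictly increasing cut points")

    score = genotypes @ w
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros(n)
    noise = rng.standard_normal(n)
    u_py = rng.random(n)
    dos_q = genotypes[:, quantity_snp] if n_snps > quantity_snp else np.zeros(n)

    def realize(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        liab = s * z + noise
        if thresholds is not None:
            cuts = np.asarray(thresholds, dtype=float)
        else:
            p = np.asarray(status_probs, dtype=float)
            cuts = np.quantile(liab, [p[0], p[0] + p[1]])
        status = np.where(liab <= cuts[0], ph.NEVER,
                          np.where(liab <= cuts[1], ph.FORMER, ph.CURRENT))
        mean = np.where(status == ph.CURRENT, packyear_means[1], packyear_means[0])
        mean = mean * (1.0 + quantity_effect * dos_q)
        py = stats.gamma.ppf(u_py, packyear_shape, scale=mean / packyear_shape)
        py = np.where(status == ph.NEVER, 0.0, py)
        pheno = ph.derive_smoking_phenotype_vector(status, py)
        return status, py, pheno

    target = score_r2
    s = np.sqrt(target / (1 - target)) if (target > 0 and sd > 0) else 0.0
    if s > 0:
        for _ in range(12):
            _, _, pheno = realize(s)
            r = np.corrcoef(pheno, score)[0, 1]
            achieved = r * r
            if achieved > 0 and abs(achieved - target) < 0.02 * target:
                break
            s *= np.sqrt(target / max(achieved, 1e-6))
            s = min(s, 5.0)
    status, py, _ = realize(s)
    return status, py


# ---------------------------------------------------------------------------
# planted truth and methylation


_CHROMS = np.arange(1, 23)


def make_truth(config: SimulationConfig, rng: np.random.Generator) -> CohortTruth:
    """Draw the planted per-site parameters and the mQTL instrument table."""
    m = config.n_sites
    site_ids = pd.Index([f"cg{j:08d}" for j in range(m)], name="site_id")
    chrom = rng.choice(_CHROMS, size=m)
    pos = rng.integers(1_000_000, 200_000_000, size=m)
    genes = np.array(
        ["".join(rng.choice(list(string.ascii_uppercase), size=4)) for _ in range(m)]
    )
    annotation = pd.DataFrame(
        {"chr": chrom, "pos": pos, "gene": genes, "gene_region": "Body"},
        index=site_ids,
    )

    tau = np.zeros(m)
    n_sig = config.n_signal_sites
    mag = rng.uniform(0.3, 1.0, size=n_sig) * config.tau_scale / 0.65
    sign = np.where(rng.random(n_sig) < config.frac_hypo, -1.0, 1.0)
    tau[:n_sig] = sign * mag

    mu0 = rng.uniform(-2.5, 2.5, size=m)
    cell_coefs = rng.normal(0.0, config.cell_effect_sd, size=(m, config.n_cell_types - 1))
    batch_offsets = rng.normal(0.0, config.batch_effect_sd, size=(m, config.n_batches))

    lo, hi = config.mqtls_per_site
    counts = rng.integers(lo, hi + 1, size=m)
    rows = []
    snp_counter = 0
    bases = np.array(list("ACGT"))
    for j in range(m):
        for _ in range(counts[j]):
            cis = rng.random() < config.cis_fraction
            if cis:
                c = chrom[j]
                p = int(pos[j] + rng.integers(-900_000, 900_000))
            else:
                c = int(rng.choice(_CHROMS[_CHROMS != chrom[j]]))
                p = int(rng.integers(1_000_000, 200_000_000))
            ea = rng.choice(4)
            oa = (ea + rng.integers(1, 4)) % 4
            rows.append(
                (
                    f"rs{9_000_000 + snp_counter}",
                    site_ids[j],
                    c,
                    max(p, 1),
                    float(rng.uniform(*config.mqtl_freq_range)),
                    float(rng.normal(0.0, config.mqtl_effect_sd)),
                    bases[ea],
                    bases[oa],
                )
            )
            snp_counter += 1
    mqtls = pd.DataFrame(
        rows,
        columns=["snp", "site_id", "chr", "pos", "eaf", "gamma",
                 "effect_allele", "other_allele"],
    )
    mediator_sites = list(site_ids[:config.n_mediator_sites])
    return CohortTruth(
        site_ids=site_ids, mu0=mu0, tau=tau,
        theta_direct=config.theta_direct, theta_med=config.theta_med,
        mediator_sites=mediator_sites, cell_coefs=cell_coefs,
        batch_offsets=batch_offsets, mqtls=mqtls, annotation=annotation,
    )


def simulate_cell_proportions(
    n: int, n_cell_types: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet leukocyte proportions; rows sum to one."""
    alpha = concentration * np.linspace(1.5, 0.5, n_cell_types)
    return rng.dirichlet(alpha, size=n)


def _mqtl_site_term(truth: CohortTruth, dosages: pd.DataFrame) -> np.ndarray:
    """Per-site genetic contribution sum_k gamma_k * dosage_k, (n_sites, n)."""
    n = dosages.shape[0]
    term = np.zeros((len(truth.site_ids), n))
    site_pos = {s: j for j, s in enumerate(truth.site_ids)}
    dos = dosages.to_numpy(dtype=float)
    col = {s: j for j, s in enumerate(dosages.columns)}
    for snp, site, gamma in truth.mqtls[["snp", "site_id", "gamma"]].itertuples(index=False):
        term[site_pos[site]] += gamma * dos[:, col[snp]]
    return term


def simulate_methylation(
    smoking_phenotype: np.ndarray,
    mqtl_term: np.ndarray,
    cell_props: np.ndarray,
    batch_ids: np.ndarray,
    truth: CohortTruth,
    rng: np.random.Generator,
    residual_sd: float = 0.5,
    person_intercept: np.ndarray | None = None,
    sample_ids=None,
) -> MethylationMatrix:
    """Generate one wave's beta matrix from the planted linear M-value model."""
    pheno = np.asarray(smoking_phenotype, dtype=float)
    n = len(pheno)
    m = len(truth.site_ids)
    if mqtl_term.shape != (m, n) or cell_props.shape[0] != n:
        raise ValueError("inconsistent dimensions between phenotype, mQTL term "
                         "and cell proportions")
    M = truth.mu0[:, None] + truth.tau[:, None] * pheno[None, :] + mqtl_term
    M += truth.cell_coefs @ cell_props[:, :-1].T
    M += truth.batch_offsets[:, np.asarray(batch_ids)]
    if person_intercept is not None:
        M += person_intercept
    if residual_sd > 0:
        M += rng.normal(0.0, residual_sd, size=(m, n))
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    beta = pd.DataFrame(ph.m_to_beta(M), index=truth.site_ids, columns=sample_ids)
    return MethylationMatrix(beta, truth.annotation)


# ---------------------------------------------------------------------------
# second wave


def simulate_wave2_smoking(
    status_w1: np.ndarray,
    packyears_w1: np.ndarray,
    transition_probs: np.ndarray,
    rng: np.random.Generator,
    wave_years: float = 11.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample wave-2 status from the transition matrix and accumulate pack-years.

    Quitting freezes pack-years; continuing or resuming smokers accumulate;
    never-smokers who start acquire a small positive dose.
    """
    t = np.asarray(transition_probs, dtype=float)
    validate_transition_matrix(t)
    status_w1 = np.asarray(status_w1, dtype=object)
    py1 = np.asarray(packyears_w1, dtype=float)
    n = len(status_w1)
    idx = np.array([ph.STATUSES.index(s) for s in status_w1])
    u = rng.random(n)
    cum = np.cumsum(t[idx], axis=1)
    nxt = (u[:, None] > cum).sum(axis=1)
    status_w2 = np.array(ph.STATUSES, dtype=object)[nxt]

    py2 = py1.copy()
    add = rng.gamma(2.0, 1.0, size=n)  # unit-mean-2 gamma, scaled per pathway below
    started = (idx == 0) & (nxt > 0)
    py2[started] = add[started] * 1.5                      # new smokers: small dose
    resumed = (idx == 1) & (nxt == 2)
    py2[resumed] = py1[resumed] + add[resumed] * 2.0       # resumed partway through
    continuing = (idx == 2) & (nxt == 2)
    py2[continuing] = py1[continuing] + add[continuing] * wave_years * 0.75 / 2.0
    if np.any(py2 < py1):
        raise AssertionError("pack-years decreased between waves")
    return status_w2, py2


# ---------------------------------------------------------------------------
# outcome and nested case-control sampling


def simulate_outcome(
    phenotype: np.ndarray,
    mediator_m_sum: np.ndarray,
    theta_direct: float,
    theta_med: float,
    case_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary outcome: P(case) = expit(c + theta_direct*smoking + theta_med*sum M).

    The intercept c is solved so the population incidence matches
    ``case_fraction``.
    """
    lp = theta_direct * np.asarray(phenotype, float) + theta_med * np.asarray(
        mediator_m_sum, float
    )
    lp = lp - lp.mean()

    def gap(c):
        return special.expit(c + lp).mean() - case_fraction

    c = optimize.brentq(gap, -30.0, 30.0)
    return rng.random(len(lp)) < special.expit(c + lp)


def match_controls(
    case_ids,
    pool_ids,
    sex: pd.Series,
    age: pd.Series,
    caliper: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Greedy nearest-age, same-sex matching without replacement.

    Cases with no eligible control get one retry at a doubled caliper; if that
    also fails the case is dropped with a logged warning.
    """
    pool = list(pool_ids)
    used: set = set()
    rows = []
    matchset = 0
    order = list(case_ids)
    rng.shuffle(order)
    for cid in order:
        best, best_gap = None, np.inf
        for widen, cal in enumerate((caliper, 2 * caliper)):
            for pid in pool:
                if pid in used or sex[pid] != sex[cid]:
                    continue
                gap = abs(age[pid] - age[cid])
                if gap <= cal and gap < best_gap:
                    best, best_gap = pid, gap
            if best is not None:
                if widen:
                    logger.warning("case %s matched only after widening caliper to %.1f",
                                   cid, 2 * caliper)
                break
        if best is None:
            logger.warning("case %s dropped: no eligible control", cid)
            continue
        used.add(best)
        rows.append((cid, best, matchset))
        matchset += 1
    return pd.DataFrame(rows, columns=["case_id", "control_id", "matchset"])


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, CohortTruth]:
    """Generate the full two-wave cohort and its nested case-control sample."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    (rng_truth, rng_geno, rng_smoke, rng_meth1, rng_wave2,
     rng_meth2, rng_outcome, rng_misc) = rngs

    n = config.n_individuals
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="id")
    truth = make_truth(config, rng_truth)

    geno = simulate_genotypes(config.allele_freqs, n, rng_geno)
    genotypes = pd.DataFrame(geno, index=ids, columns=list(SMOKING_SNPS))
    mqtl_freqs = truth.mqtls["eaf"].to_numpy()
    mqtl_dos = simulate_genotypes(mqtl_freqs, n, rng_geno)
    mqtl_dosages = pd.DataFrame(mqtl_dos, index=ids, columns=truth.mqtls["snp"])
    mqtl_term = _mqtl_site_term(truth, mqtl_dosages)

    status1, py1 = simulate_smoking(
        geno, config.score_weights, rng_smoke,
        status_probs=config.status_probs, score_r2=config.score_r2,
    )
    status2, py2 = simulate_wave2_smoking(
        status1, py1, config.wave_transition_probs, rng_wave2, config.wave_years
    )

    sex = rng_misc.integers(0, 2, size=n)
    age1 = np.clip(rng_misc.normal(config.age_mean, config.age_sd, size=n), 30, 80)
    age2 = age1 + config.wave_years

    cells1 = simulate_cell_proportions(n, config.n_cell_types, config.cell_concentration, rng_meth1)
    cells2 = simulate_cell_proportions(n, config.n_cell_types, config.cell_concentration, rng_meth2)
    batch1 = rng_meth1.integers(0, config.n_batches, size=n)
    batch2 = rng_meth2.integers(0, config.n_batches, size=n)
    person = (
        rng_meth1.normal(0.0, config.person_sd, size=(config.n_sites, n))
        if config.person_sd > 0 else None
    )

    pheno1 = ph.derive_smoking_phenotype_vector(status1, py1)
    pheno2 = ph.derive_smoking_phenotype_vector(status2, py2)
    meth1 = simulate_methylation(
        pheno1, mqtl_term, cells1, batch1, truth, rng_meth1,
        residual_sd=config.residual_sd, person_intercept=person, sample_ids=ids,
    )
    meth2 = simulate_methylation(
        pheno2, mqtl_term, cells2, batch2, truth, rng_meth2,
        residual_sd=config.residual_sd, person_intercept=person, sample_ids=ids,
    )

    med_idx = [truth.site_ids.get_loc(s) for s in truth.mediator_sites]
    med_sum = ph.beta_to_m(meth1.beta.to_numpy()[med_idx]).sum(axis=0)
    case = simulate_outcome(
        pheno1, med_sum, config.theta_direct, config.theta_med,
        config.case_fraction, rng_outcome,
    )

    case_ids = list(ids[case])
    if len(case_ids) > config.n_cases:
        case_ids = list(rng_outcome.choice(case_ids, size=config.n_cases, replace=False))
    sex_s = pd.Series(sex, index=ids)
    age_s = pd.Series(age1, index=ids)
    matched = match_controls(
        case_ids, ids[~case], sex_s, age_s, config.age_caliper, rng_outcome
    )

    pheno = pd.DataFrame(
        {
            "sex": sex,
            "age_w1": age1,
            "age_w2": age2,
            "status_w1": status1,
            "status_w2": status2,
            "packyears_w1": py1,
            "packyears_w2": py2,
            "phenotype_w1": pheno1,
            "phenotype_w2": pheno2,
            "case": case,
        },
        index=ids,
    )
    pheno["smoking_change"] = [
        ph.classify_smoking_change(a, b) for a, b in zip(status1, status2)
    ]
    pheno["matchset"] = pd.array([pd.NA] * n, dtype="Int64")
    for cid, kid, mset in matched.itertuples(index=False):
        pheno.loc[cid, "matchset"] = mset
        pheno.loc[kid, "matchset"] = mset

    cell_cols = [f"cell{k}" for k in range(config.n_cell_types)]
    cohort = Cohort(
        pheno=pheno,
        genotypes=genotypes,
        meth_w1=meth1,
        meth_w2=meth2,
        cells_w1=pd.DataFrame(cells1, index=ids, columns=cell_cols),
        cells_w2=pd.DataFrame(cells2, index=ids, columns=cell_cols),
        batch_w1=batch1,
        batch_w2=batch2,
        mqtl_dosages=mqtl_dosages,
        matched=matched,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# summary statistics for two-sample MR


def simulate_mqtl_summary(
    truth: CohortTruth,
    rng: np.random.Generator,
    n: int = 5101,
    sigma_m: float = 1.0,
) -> pd.DataFrame:
    """mQTL summary statistics as measured in a large external methylation GWAS."""
    tab = truth.mqtls.copy()
    f = tab["eaf"].to_numpy()
    se = sigma_m / np.sqrt(2 * f * (1 - f) * n)
    gamma_hat = tab["gamma"].to_numpy() + rng.normal(0.0, se)
    tab["beta"] = gamma_hat
    tab["se"] = se
    tab["p"] = 2 * stats.norm.sf(np.abs(gamma_hat / se))
    ann = truth.annotation
    tab["cpg_chr"] = ann.loc[tab["site_id"], "chr"].to_numpy()
    tab["cpg_pos"] = ann.loc[tab["site_id"], "pos"].to_numpy()
    return tab.rename(columns={"site_id": "cpg_id"})[
        ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
         "beta", "se", "p", "cpg_id", "cpg_chr", "cpg_pos"]
    ]


def simulate_outcome_gwas(
    truth: CohortTruth,
    rng: np.random.Generator,
    n: int = 85716,
    n_cases: int = 29266,
    flip_fraction: float = 0.5,
) -> pd.DataFrame:
    """Lung-cancer GWAS summary statistics for the mQTL instruments.

    Under the planted model the true per-allele log-OR of each mQTL is
    theta_med * gamma (no pleiotropic path).  A random subset of rows is
    reported with swapped alleles and flipped signs to exercise harmonization.
    """
    tab = truth.mqtls.copy()
    f = tab["eaf"].to_numpy()
    phi = n_cases / n
    se = 1.0 / np.sqrt(2 * f * (1 - f) * n * phi * (1 - phi))
    true_g = truth.theta_med * tab["gamma"].to_numpy()
    g_hat = true_g + rng.normal(0.0, se)
    flip = rng.random(len(tab)) < flip_fraction
    ea = np.where(flip, tab["other_allele"], tab["effect_allele"])
    oa = np.where(flip, tab["effect_allele"], tab["other_allele"])
    beta = np.where(flip, -g_hat, g_hat)
    return pd.DataFrame(
        {
            "snp": tab["snp"],
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(beta / se)),
        }
    )
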