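# Methods

## The synthetic cohort

The generator (`simcohort`) emulates a two-wave population survey with a
nested case-control study drawn from it.  It exists so that every stage of
the analysis chain can be tested against known truth; its defaults encode
the study conditions the package targets.

**Genotypes.** Three smoking-associated SNPs (initiation, quantity,
cessation; default allele frequencies 0.20 / 0.35 / 0.08, roughly the
European frequencies of the canonical variants) drawn under
Hardy–Weinberg as two Bernoulli draws per individual, plus 1–9 mQTLs per
CpG site (half cis within 1 Mb, half trans) with per-allele M-value
effects N(0, 0.30).

**Smoking.** A liability model: standardized genetic score times a scale
s plus standard normal noise, cut at the empirical quantiles that give
50% never / 25% former / 25% current smokers.  Pack-years are Gamma
(shape 2) with mean 12 (former) or 18 (current), inflated 15% per
quantity-SNP allele.  The scale s is calibrated by a deterministic fixed
point on the drawn sample so that the 7-level phenotype regressed on the
raw score attains R² ≈ 0.018 — the variance share a 3-SNP score
realistically explains, and deliberately a *weak* instrument; there is no
clean closed form for the attenuation that the ordinal coarsening and the
Gamma pack-year noise impose on the liability R², hence the calibration.

**Methylation.** Generated linearly on the M-value scale, where planted
effects are well defined, then stored as beta = 2^M/(2^M+1) ∈ (0,1):

M_ij = μ0_j + τ_j·smoking_i + Σ_k γ_jk·dosage_ik + cell term + batch term
      + u_ij + ε_ij

with per-site baselines μ0 ~ U(−2.5, 2.5), six Dirichlet cell-type
proportions entering through five identifiable components, four batches
with per-site offsets (SD 0.3), a person-by-site random intercept u
(SD 0.3) shared across waves (this is what makes repeated measurements
informative), and residual SD 0.35.  76 of 1000 sites carry a smoking
effect τ, 83% of them negative (smoking predominantly hypomethylates),
with |τ| in ≈ 0.12–0.38 M-units per phenotype level — chosen so that,
near beta 0.5, the implied per-level beta-value effects span roughly
0.003–0.05, the magnitude range a well-powered scan of ~130 controls
detects at 5×10⁻⁸, as in the emulated design.

**Second wave.** Status transitions follow a 3×3 matrix whose default
rows are the observed marginals of a 128-control roster (never: 59/63
stay, 3/63 → former, 1/63 → current; former: 6/35 resume; current: 16/30
quit).  Pack-years never decrease: quitting freezes them, continuing
smokers accumulate ≈ 0.75 packs/day over the 11-year gap, starters
acquire a small positive dose.  Wave-2 methylation is regenerated from
wave-2 exposure with the same person intercepts.

**Outcome and matching.** P(case) = expit(c + θ_A·smoking + θ_M·Σ M over
the mediator set), with c solved by root finding to hit the target
incidence (default 7%).  Defaults: θ_A = 0.5 log-OR per phenotype level
(OR ≈ 20 for top-level current smokers vs never, a realistic
smoking–lung-cancer gradient) and **θ_M = 0** — no methylation→cancer
effect, so mediation and second-step MR run under a true null by default.
Each case gets one never-used control of the same sex within ±3 years of
age (greedy nearest-age); a case with no eligible control gets one retry
at a doubled caliper, then is dropped with a logged warning.

## Analysis stages

**Surrogate variables.** Every site's beta is residualized on the model
terms, the residual matrix is centered and its top k right singular
vectors (k = 12 by default) become covariates.  This deterministic
residual-SVD variant is used instead of the iteratively re-weighted
original: it is reproducible to the sign convention (largest-magnitude
element positive) and recovers a planted batch vector with |r| > 0.95 in
tests.  The iterative variant is a non-goal.

**Linear scan.** One shared QR factorization per design; per-site
coefficients, t-tests, p < 5×10⁻⁸ genome-wide flag and optional p·m <
0.05 Bonferroni flag.  p-values below the smallest positive normal double
are reported as that value with an underflow flag.  Rank-deficient
designs raise naming the collinear columns.

**Logistic scan.** In-package IRLS (relative deviance tolerance 1e-10,
max 100 iterations), validated against statsmodels maximum likelihood to
1e-6.  Quasi-complete separation (diverging coefficients or vanishing
information) flags the site with missing estimates instead of raising.
Coefficients are log-odds per beta 0→1; the table adds exp(coef/100), the
OR per 1% methylation.  Whether the cancer scan adjusts for surrogate
variables and cell counts is config-controlled; the default cancer model
adjusts for sex, age and cell composition only.

**LMRSE.** Point estimates are exactly pooled OLS; only the variance is
robustified (CR1 factor G/(G−1)·(N−1)/(N−K), t with G−1 df — standard
practice at ~120 clusters; the reference analysis names neither choice,
so both are stated here).  The exposure is the wave-1 phenotype for both
waves' rows; a wave indicator is included by default.  With singleton
clusters the CR1 variance equals HC1 exactly.

**LMEM.** Random-intercept REML profiled over λ = σ²_u/σ²_e: for each
candidate λ all cross-products reduce to cluster sums, so an objective
evaluation is one p×p solve; the 1-D bounded minimization runs on log λ
with tolerance 1e-8, and the λ→0 boundary is checked explicitly.
Validated against statsmodels MixedLM.  On balanced two-wave panels with
person-constant exposure the GLS fixed effect coincides with pooled OLS,
which the tests assert to 1e-6.  Only a random intercept is modeled; no
AR(1) or unstructured covariance.

**Change analysis.** OLS of (wave-2 − wave-1) beta on the numeric 0/1/2
change variable, unadjusted by default (a covariate switch exists).  At a
site hypomethylated by smoking, quitters rebound upward relative to
increasers, so the change coefficient is negative — the tests assert this
sign convention on simulated cohorts.

**Mediation.** The product-method estimator treats the outcome as rare;
the case-control design it emulates is ~50% cases by design, and the
printed relative effects are consistent with the rare-outcome product
formula, so that is the default, with the Monte-Carlo counterfactual
simulation estimator available (`estimator="simulation"`) both as an
honest non-rare alternative and as the cross-check the tests run (the two
agree to ~0.02 on rare-outcome data).  With no exposure–mediator
interaction NDE + NIE = TE exactly on the log scale.  CIs are percentile
bootstrap over jointly refitted models (B = 1000 by default); a site is
"identified" when its NIE CI excludes zero — no explicit identification
rule is published for the screen this mirrors, so the 95% CI rule is this
package's choice.  TE within 1e-12 of zero makes the relative effect NaN,
never infinite.

**MR.** The genetic score is an unweighted allele count (no published
weighting).  2SLS recomputes stage-2 residuals with the observed exposure
(standard 2SLS variance); first-stage F below 10 flags but does not
suppress the result — the emulated design itself reports at F = 2.4.
Harmonization matches effect alleles by letter, flips swapped reports,
resolves palindromic SNPs by frequency when |eaf − 0.5| > 0.08 and drops
them otherwise.  The cis window is 1 Mb inclusive.  Only fixed-effect IVW
is provided: with 1–9 instruments per site, random-effects heterogeneity
estimates are too fragile.  Variance explained from summary statistics is
Σ 2f(1−f)γ².  With a weak instrument, two-sample IVW bias runs toward the
null — which is why a null MR result after a positive mediation screen is
the expected signature on the default (θ_M = 0) cohorts.

## Numerical and design notes

- Pack-year band edges: the printed categories ("≤10.0", "10.1–20.0",
  "≥20.1") leave real values in (10.0, 10.1) and (20.0, 20.1) unassigned;
  the operational rule is half-open — (10, 20] middle band, > 20 top band.
  Missing pack-years for an ever-smoker yield a missing phenotype
  (excluded downstream), never an imputation.
- Matched analysis: the scans use unconditional models adjusting for age
  and sex, consistent with the odds ratios the emulated study appears to
  report; matchset ids are retained so conditional analyses remain
  possible.
- Seeds: one global seed fans out via `numpy.random.SeedSequence` to
  per-stage substreams; identical config + seed reproduces every output
  byte for byte (stage timings are therefore kept out of the written
  manifest).
- Beta/M conversion rejects values outside (0,1) unless an explicit
  clamp-at-1e-6 flag is set.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own defaults for routine verification: EWAS
type-I error over 1000 null sites at n = 128; second-step MR type-I over
1000 summary-statistic replicates with 1–9 instruments each; 2SLS
coverage over 500 replicates at n = 2000 under strong unmeasured
confounding with a strong instrument (weak-instrument undercoverage is a
separate, documented behavior); LMRSE-vs-LMEM agreement over 1000 sites
of a 120-person two-wave panel with 10% second-wave dropout; cluster
bootstrap with 2000 replicates on a 50-person panel.

## What passing tests do and do not show

The generator's linear M-scale model with Gaussian noise, Dirichlet cell
proportions and categorical batches omits much of real array data:
probe-level artifacts, heteroscedastic beta-value noise outside the
0.2–0.8 range (the analyses run on beta-values precisely because the
emulated study did, and inherit that caveat), population stratification,
correlated CpGs in LD with shared mQTLs, and selection into the cohort.
Passing tests therefore certify the *estimators* — their algebra, their
error control under the stated model — not the robustness of any
real-data conclusion to violations of that model.  No laboratory
preprocessing (IDAT handling, normalization, QC) is modeled or performed.
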