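"""Two-step MR: genetic score, instrument strength, 2SLS under confounding,
Wald ratio, IVW, harmonization and the cis filter."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from methylcause import mr


class TestGeneticScore:
    def test_dosage_arithmetic(self):
        g = pd.DataFrame([[0, 0, 0], [2, 2, 2], [2, 1, 2]],
                         columns=["rs1", "rs2", "rs3"])
        s = mr.build_genetic_score(g)
        assert list(s) == [0.0, 6.0, 5.0]
        sw = mr.build_genetic_score(g, weights=[0.5, 1.0, 0.0])
        assert sw.iloc[2] == pytest.approx(2.0)

    def test_missing_snp_and_missing_genotype(self):
        g = pd.DataFrame({"rs1": [0, 1, np.nan], "rs2": [2, 0, 1]})
        with pytest.raises(KeyError):
            mr.build_genetic_score(g, snps=["rs1", "rs9"])
        s = mr.build_genetic_score(g)
        assert len(s) == 2  # missing-genotype individual excluded


class TestInstrumentStrength:
    def test_perfect_instrument(self, rng):
        s = rng.normal(size=100)
        r2, f = mr.instrument_strength(s, s)
        assert r2 == 1.0 and np.isinf(f)

    def test_null_instrument(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=10_000)
        e = rng.normal(size=10_000)
        r2, f = mr.instrument_strength(s, e)
        assert r2 < 0.001 and f < 5

    def test_matches_anova_f_from_statsmodels(self, rng):
        s = rng.normal(size=200)
        e = 0.2 * s + rng.normal(size=200)
        r2, f = mr.instrument_strength(s, e)
        ref = sm.OLS(e, sm.add_constant(s)).fit()
        assert r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert f == pytest.approx(ref.fvalue, abs=1e-8)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            mr.instrument_strength(np.ones(10), np.arange(10.0))


class TestTwoStageLeastSquares:
    def test_just_identified_equals_wald_of_reduced_forms(self):
        rng = np.random.default_rng(2)
        n = 500
        z = rng.integers(0, 2, n).astype(float)
        a = 0.5 * z + rng.normal(size=n)
        y = -0.3 * a + rng.normal(size=n)
        res = mr.two_stage_least_squares(z, a, y)
        num = np.polyfit(z, y, 1)[0]   # reduced form
        den = np.polyfit(z, a, 1)[0]   # first stage
        assert res.estimate == pytest.approx(num / den, abs=1e-10)

    def test_unbiased_under_confounding_where_ols_is_biased(self):
        rng = np.random.default_rng(4)
        n = 10_000
        tau = -0.2
        z = rng.binomial(2, 0.3, size=n).astype(float)
        u = rng.normal(size=n)
        a = 0.4 * z + 0.9 * u + rng.normal(size=n)
        m = tau * a + 1.2 * u + rng.normal(size=n)
        tsls = mr.TwoStageLeastSquares().fit(z, a, m)
        assert abs(tsls.estimate_ - tau) < 2 * tsls.se_
        ols = sm.OLS(m, sm.add_constant(a)).fit()
        assert abs(ols.params[1] - tau) > 4 * ols.bse[1]  # badly biased
        assert not tsls.weak_instrument_

    def test_weak_instrument_flagged_but_reported(self):
        rng = np.random.default_rng(6)
        n = 2000
        z = rng.binomial(2, 0.3, n).astype(float)
        a = 0.03 * z + rng.normal(size=n)
        m = 0.1 * a + rng.normal(size=n)
        tsls = mr.TwoStageLeastSquares().fit(z, a, m)
        assert tsls.weak_instrument_
        assert np.isfinite(tsls.estimate_) and np.isfinite(tsls.se_)

    def test_constant_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            mr.two_stage_least_squares(np.ones(50), rng.normal(size=50),
                                       rng.normal(size=50))


class TestWaldRatio:
    def test_hand_arithmetic(self):
        res = mr.wald_ratio(0.5, 0.1, 0.05)
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        assert res.method == "wald" and res.n_instruments == 1

    def test_null_outcome_gives_unit_odds_ratio(self):
        res = mr.wald_ratio(0.5, 0.0, 0.05)
        assert res.estimate == 0.0 and res.odds_ratio == pytest.approx(1.0)

    def test_harmonized_sign_flip_invariance(self):
        a = mr.wald_ratio(0.5, 0.1, 0.05)
        b = mr.wald_ratio(-0.5, -0.1, 0.05)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.se == pytest.approx(b.se)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(0.0, 0.1, 0.05)


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        w = mr.wald_ratio(0.5, 0.1, 0.05)
        i = mr.ivw([0.5], [0.1], [0.05])
        assert i.estimate == w.estimate and i.se == w.se

    def test_constant_ratio_recovered(self, rng):
        g = rng.uniform(0.2, 0.8, 5)
        c = -0.35
        res = mr.ivw(g, c * g, rng.uniform(0.01, 0.1, 5))
        assert res.estimate == pytest.approx(c, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self, rng):
        g = rng.uniform(0.2, 0.8, 5)
        G = -0.3 * g + rng.normal(0, 0.05, 5)
        s = rng.uniform(0.02, 0.1, 5)
        res = mr.ivw(g, G, s)
        w = 1 / s**2
        oracle = np.sum(w * g * G) / np.sum(w * g**2)
        oracle_se = np.sqrt(1 / np.sum(w * g**2))
        assert res.estimate == pytest.approx(oracle, abs=1e-10)
        assert res.se == pytest.approx(oracle_se, abs=1e-10)

    def test_subset_sign_flip_invariance(self, rng):
        g = rng.uniform(0.2, 0.8, 6)
        G = -0.3 * g + rng.normal(0, 0.05, 6)
        s = rng.uniform(0.02, 0.1, 6)
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        a = mr.ivw(g, G, s)
        b = mr.ivw(g * flip, G * flip, s)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw([0.5, 0.4], [0.1], [0.05])


def instrument_table(chroms, positions, cpg_chr=3, cpg_pos=98_251_294, **kw):
    n = len(chroms)
    return pd.DataFrame({
        "snp": [f"rs{j}" for j in range(n)],
        "chr": chroms,
        "pos": positions,
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.5] * n,
        "se": [0.05] * n,
        "p": [1e-8] * n,
        "cpg_id": ["cgX"] * n,
        "cpg_chr": [cpg_chr] * n,
        "cpg_pos": [cpg_pos] * n,
    })


class TestCisFilter:
    def test_trans_chromosome_removed_and_boundary_inclusive(self):
        tab = instrument_table([3, 3, 7], [1_000_000, 3_000_000, 1_000_000],
                               cpg_chr=3, cpg_pos=2_000_000)
        out = mr.filter_cis(tab, 3, 2_000_000, window=1_000_000)
        assert list(out["snp"]) == ["rs0", "rs1"]  # exactly at the window kept

    def test_published_instrument_chromosomes_leave_one_cis(self):
        """A CpG on chromosome 3 with instruments on 7;3;9;4;4;4;2 keeps
        exactly one cis instrument at any window."""
        chroms = [7, 3, 9, 4, 4, 4, 2]
        tab = instrument_table(chroms, [98_300_000] * 7)
        out = mr.filter_cis(tab, 3, 98_251_294, window=1_000_000)
        assert len(out) == 1 and out["chr"].iloc[0] == 3


class TestHarmonization:
    def test_swapped_alleles_flip_sign(self):
        inst = instrument_table([1, 1], [1000, 2000])
        outcome = pd.DataFrame({
            "snp": ["rs0", "rs1"],
            "effect_allele": ["A", "G"],   # rs1 reported on the other allele
            "other_allele": ["G", "A"],
            "beta": [0.1, -0.1],
            "se": [0.05, 0.05],
            "p": [0.1, 0.1],
        })
        h = mr.harmonize(inst, outcome)
        assert h.loc[0, "Gamma"] == pytest.approx(0.1)
        assert h.loc[1, "Gamma"] == pytest.approx(0.1)  # flipped back

    def test_ambiguous_palindromic_dropped(self):
        inst = instrument_table([1], [1000])
        inst.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        inst.loc[0, "eaf"] = 0.5
        outcome = pd.DataFrame({
            "snp": ["rs0"], "effect_allele": ["A"], "other_allele": ["T"],
            "beta": [0.1], "se": [0.05], "p": [0.1]})
        assert len(mr.harmonize(inst, outcome)) == 0

    def test_allele_mismatch_raises(self):
        inst = instrument_table([1], [1000])
        outcome = pd.DataFrame({
            "snp": ["rs0"], "effect_allele": ["C"], "other_allele": ["T"],
            "beta": [0.1], "se": [0.05], "p": [0.1]})
        with pytest.raises(ValueError, match="mismatch"):
            mr.harmonize(inst, outcome)


class TestSecondStepScreen:
    def test_site_without_outcome_stats_is_untestable(self):
        inst = instrument_table([1], [1000])
        outcome = pd.DataFrame({
            "snp": ["rs999"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta": [0.1], "se": [0.05], "p": [0.1]})
        res = mr.mr_second_step_screen(inst, outcome, bonferroni_m=13)
        assert res.loc["cgX", "status"] == "untestable"

    def test_planted_causal_site_detected(self):
        rng = np.random.default_rng(1)
        theta = 0.5  # log-OR per unit M-value
        g = rng.uniform(0.3, 0.8, 4)
        se_G = np.full(4, 0.02)
        inst = instrument_table([1] * 4, [1000] * 4, cpg_chr=1, cpg_pos=1500)
        inst["beta"] = g
        outcome = pd.DataFrame({
            "snp": inst["snp"], "effect_allele": ["A"] * 4,
            "other_allele": ["G"] * 4,
            "beta": theta * g + rng.normal(0, se_G),
            "se": se_G, "p": [0.1] * 4})
        res = mr.mr_second_step_screen(inst, outcome, bonferroni_m=13)
        row = res.loc["cgX"]
        assert row["status"] == "ok" and row["method"] == "ivw"
        assert row["bonferroni"]
        assert abs(row["estimate"] - theta) < 3 * row["se"]

    def test_variance_explained_from_summary_stats(self):
        # sum of 2 f (1-f) gamma^2 over instruments
        ve = mr.variance_explained_summary([0.3, 0.4], [0.5, -0.2], var_m=1.0)
        expected = 2 * 0.3 * 0.7 * 0.25 + 2 * 0.4 * 0.6 * 0.04
        assert ve == pytest.approx(expected)
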