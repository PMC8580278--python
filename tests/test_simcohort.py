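"""Generator checks: genotypes, smoking liability, methylation model,
second wave, outcome and matched sampling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcause import phenotypes as ph
from methylcause import simcohort as sc
from methylcause._linalg import batch_ols, irls_logistic, t_pvalues


class TestGenotypes:
    def test_support_and_hardy_weinberg_mean(self, rng):
        g = sc.simulate_genotypes([0.5], 4, rng)
        assert g.shape == (4, 1) and set(np.unique(g)) <= {0, 1, 2}
        g = sc.simulate_genotypes([0.3], 100_000, rng)
        # mean dosage 2f with binomial MC SE sqrt(2 f (1-f) / n)
        se = np.sqrt(2 * 0.3 * 0.7 / 100_000)
        assert abs(g.mean() - 0.6) < 3 * se

    def test_degenerate_frequency(self, rng):
        g = sc.simulate_genotypes([1 - 1e-12], 100, rng)
        assert np.all(g == 2)
        with pytest.raises(ValueError):
            sc.simulate_genotypes([1.0], 10, rng)
        with pytest.raises(ValueError):
            sc.simulate_genotypes([0.0], 10, rng)


class TestSmoking:
    def test_zero_weights_break_genotype_link(self, rng):
        g = sc.simulate_genotypes([0.3, 0.3, 0.3], 10_000, rng)
        status, _ = sc.simulate_smoking(g, [0, 0, 0], rng, score_r2=0.018,
                                        quantity_effect=0.0)
        tab = pd.crosstab(pd.Series(status), pd.Series(g[:, 0]))
        _, p, _, _ = stats.chi2_contingency(tab)
        assert p > 1e-3

    def test_score_r2_calibration(self, rng):
        g = sc.simulate_genotypes([0.2, 0.35, 0.08], 10_000, rng)
        status, py = sc.simulate_smoking(g, [1, 1, 1], rng, score_r2=0.018)
        pheno = ph.derive_smoking_phenotype_vector(status, py)
        score = g.sum(axis=1)
        r2 = np.corrcoef(pheno, score)[0, 1] ** 2
        assert r2 == pytest.approx(0.018, abs=0.004)

    def test_never_smokers_have_zero_packyears(self, rng):
        g = sc.simulate_genotypes([0.3] * 3, 2000, rng)
        status, py = sc.simulate_smoking(g, [1, 1, 1], rng)
        assert np.all(py[status == ph.NEVER] == 0)
        assert np.all(py[status != ph.NEVER] > 0)

    def test_bad_thresholds_rejected(self, rng):
        g = sc.simulate_genotypes([0.3] * 3, 100, rng)
        with pytest.raises(ValueError):
            sc.simulate_smoking(g, [1, 1, 1], rng, thresholds=(1.0, 1.0))


def _plain_truth(n_sites, tau, rng, n_cell=6):
    """Truth object with only smoking effects (no cell/batch/mQTL structure)."""
    cfg = sc.SimulationConfig(
        n_individuals=10, n_sites=n_sites, n_signal_sites=0, n_mediator_sites=0,
        cell_effect_sd=0.0, batch_effect_sd=0.0, mqtl_effect_sd=0.0,
        n_cell_types=n_cell,
    )
    truth = sc.make_truth(cfg, rng)
    truth.tau = np.asarray(tau, dtype=float)
    return truth


class TestMethylation:
    def test_null_sites_give_uniform_pvalues(self, rng):
        n, m = 200, 1000
        truth = _plain_truth(m, np.zeros(m), rng)
        pheno = rng.integers(0, 7, size=n).astype(float)
        cells = sc.simulate_cell_proportions(n, 6, 10.0, rng)
        meth = sc.simulate_methylation(
            pheno, np.zeros((m, n)), cells, np.zeros(n, dtype=int), truth, rng,
            residual_sd=0.4)
        X = np.column_stack([np.ones(n), pheno])
        fit = batch_ols(X, meth.beta.to_numpy().T)
        p, _ = t_pvalues(fit.coef[1], fit.se[1], fit.df_resid)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_noise_free_negative_tau_is_monotone_decreasing(self, rng):
        m = 5
        truth = _plain_truth(m, np.full(m, -0.5), rng)
        pheno = np.arange(7.0)
        cells = np.tile(np.full(6, 1 / 6), (7, 1))
        meth = sc.simulate_methylation(
            pheno, np.zeros((m, 7)), cells, np.zeros(7, dtype=int), truth, rng,
            residual_sd=0.0)
        b = meth.beta.to_numpy()
        assert np.all(np.diff(b, axis=1) < 0)

    def test_beta_strictly_inside_unit_interval(self, small_cohort):
        cohort, _ = small_cohort
        for mm in (cohort.meth_w1, cohort.meth_w2):
            b = mm.beta.to_numpy()
            assert b.min() > 0 and b.max() < 1

    def test_planted_tau_recovered_within_2se(self, rng):
        n, m = 500, 20
        tau = np.full(m, -0.5)
        truth = _plain_truth(m, tau, rng)
        pheno = rng.integers(0, 7, size=n).astype(float)
        cells = np.tile(np.full(6, 1 / 6), (n, 1))
        meth = sc.simulate_methylation(
            pheno, np.zeros((m, n)), cells, np.zeros(n, dtype=int), truth, rng,
            residual_sd=0.3)
        M = ph.beta_to_m(meth.beta.to_numpy())
        X = np.column_stack([np.ones(n), pheno])
        fit = batch_ols(X, M.T)
        assert np.all(np.abs(fit.coef[1] - tau) < 2 * fit.se[1])


class TestWave2:
    def test_identity_transitions_keep_status(self, rng):
        status = np.array(["never", "former", "current"] * 50, dtype=object)
        py = np.where(status == "never", 0.0, 15.0)
        s2, py2 = sc.simulate_wave2_smoking(status, py, np.eye(3), rng)
        assert np.all(s2 == status)
        assert np.all(py2 >= py)

    def test_cessation_freezes_packyears(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.pheno
        quit_ = (p.status_w1 == "current") & (p.status_w2 == "former")
        assert quit_.any()
        assert np.allclose(p.loc[quit_, "packyears_w1"], p.loc[quit_, "packyears_w2"])
        assert np.all(p.packyears_w2 >= p.packyears_w1)

    def test_invalid_transition_matrices_rejected(self, rng):
        status = np.array(["never"] * 10, dtype=object)
        py = np.zeros(10)
        bad_sum = np.array([[0.5, 0.2, 0.2], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            sc.simulate_wave2_smoking(status, py, bad_sum, rng)
        back_to_never = np.array([[1, 0, 0], [0.1, 0.9, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            sc.simulate_wave2_smoking(status, py, back_to_never, rng)

    def test_person_intercept_induces_cross_wave_correlation(self):
        cfg = sc.SimulationConfig(
            n_individuals=300, n_sites=200, n_signal_sites=0, n_mediator_sites=0,
            person_sd=0.5, seed=11)
        cohort, _ = sc.simulate_cohort(cfg)
        b1 = cohort.meth_w1.beta.to_numpy()
        b2 = cohort.meth_w2.beta.to_numpy()
        cors = [np.corrcoef(b1[j], b2[j])[0, 1] for j in range(200)]
        assert np.mean(cors) > 0.2


class TestOutcomeAndMatching:
    def test_null_effects_give_no_smoking_association(self, rng):
        n = 5000
        pheno = rng.integers(0, 7, size=n).astype(float)
        case = sc.simulate_outcome(pheno, np.zeros(n), 0.0, 0.0, 0.3, rng)
        fit = irls_logistic(np.column_stack([np.ones(n), pheno]),
                            case.astype(float))
        assert abs(fit.coef[1]) < 2 * fit.se[1]

    def test_case_fraction_targeted(self, rng):
        n = 20_000
        pheno = rng.integers(0, 7, size=n).astype(float)
        case = sc.simulate_outcome(pheno, np.zeros(n), 0.5, 0.0, 0.07, rng)
        assert case.mean() == pytest.approx(0.07, abs=0.01)

    def test_matched_pairs_satisfy_sex_and_caliper(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.pheno
        assert len(cohort.matched) > 20
        for r in cohort.matched.itertuples(index=False):
            assert p.loc[r.case_id, "sex"] == p.loc[r.control_id, "sex"]
            # one widening retry allowed, so pairs are within twice the caliper
            assert abs(p.loc[r.case_id, "age_w1"] - p.loc[r.control_id, "age_w1"]) <= 6.0
            assert p.loc[r.case_id, "matchset"] == p.loc[r.control_id, "matchset"]

    def test_zero_caliper_exercises_fallback(self, rng):
        ids = pd.Index([f"i{k}" for k in range(40)])
        sex = pd.Series(rng.integers(0, 2, 40), index=ids)
        age = pd.Series(rng.normal(55, 8, 40), index=ids)
        matched = sc.match_controls(ids[:10], ids[10:], sex, age, 0.0, rng)
        assert len(matched) < 10  # continuous ages: most cases unmatched


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = sc.SimulationConfig(n_individuals=300, n_sites=50, n_signal_sites=10,
                                  n_mediator_sites=5, seed=42)
        c1, t1 = sc.simulate_cohort(cfg)
        c2, t2 = sc.simulate_cohort(cfg)
        assert np.array_equal(c1.meth_w1.beta.to_numpy(), c2.meth_w1.beta.to_numpy())
        assert np.array_equal(c1.meth_w2.beta.to_numpy(), c2.meth_w2.beta.to_numpy())
        pd.testing.assert_frame_equal(c1.pheno, c2.pheno)
        assert np.array_equal(t1.tau, t2.tau)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sc.SimulationConfig(allele_freqs=(0.2, 1.1, 0.3))
        with pytest.raises(ValueError):
            sc.SimulationConfig(residual_sd=-1.0)
        with pytest.raises(ValueError):
            sc.SimulationConfig(n_signal_sites=20, n_sites=10)
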