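"""HWE genotype simulation, score sampling, logistic fits and the validation ladder."""

import numpy as np
import pytest
from scipy.stats import chisquare

import prsprob as pp

from conftest import random_moments


class TestCaseMafFromOr:
    def test_null_odds_ratio_is_identity(self):
        assert pp.case_maf_from_or(0.3, 1.0) == pytest.approx(0.3)

    def test_odds_scaling(self):
        # control odds 1 scaled by OR=3 gives case odds 3, frequency 0.75
        assert pp.case_maf_from_or(0.5, 3.0) == pytest.approx(0.75)

    def test_rare_allele_limit(self):
        f = 1e-5
        assert pp.case_maf_from_or(f, 4.0) == pytest.approx(4 * f, rel=1e-3)


class TestSimulateGenotypes:
    def test_reproducible_under_fixed_seed(self):
        cfg = pp.ors_like_scenario(50, 60, seed=11)
        g1, l1 = pp.simulate_genotypes(cfg)
        g2, l2 = pp.simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_array_equal(l1, l2)

    def test_mean_dosage_near_hwe_expectation(self):
        f = 0.5
        cfg = pp.SimulationConfig(5000, 5000, np.array([f]), np.array([0.0]), 3)
        geno, _ = pp.simulate_genotypes(cfg)
        mean = geno.dosages.mean()
        se = np.sqrt(2 * f * (1 - f) / geno.n_individuals)
        assert abs(mean - 2 * f) < 5 * se

    def test_hwe_genotype_proportions_not_rejected(self):
        f = 0.3
        cfg = pp.SimulationConfig(25_000, 25_000, np.array([f]), np.array([0.0]), 5)
        geno, _ = pp.simulate_genotypes(cfg)
        counts = np.bincount(geno.dosages.ravel(), minlength=3)
        expected = geno.n_individuals * np.array(
            [(1 - f) ** 2, 2 * f * (1 - f), f**2]
        )
        _, p = chisquare(counts, expected)
        assert p > 0.001

    def test_case_group_enriched_for_risk_alleles(self):
        cfg = pp.SimulationConfig(
            5000, 5000, np.array([0.3]), np.array([np.log(2.0)]), 7
        )
        geno, labels = pp.simulate_genotypes(cfg)
        assert geno.dosages[labels].mean() > geno.dosages[~labels].mean()


class TestSimulateScores:
    def test_group_moments_recovered(self):
        m1 = pp.GroupMoments("cases", 0.5, 1.2)
        m0 = pp.GroupMoments("noncases", 0.0, 0.9)
        n = 100_000
        s = pp.simulate_scores(m1, m0, n, n, seed=2)
        got1 = pp.sample_moments(s.subset(case=True), "cases")
        got0 = pp.sample_moments(s.subset(case=False), "noncases")
        assert abs(got1.mean - 0.5) < 5 * m1.sd / np.sqrt(n)
        assert abs(got0.mean - 0.0) < 5 * m0.sd / np.sqrt(n)
        assert got1.variance == pytest.approx(1.2, rel=0.05)
        assert got0.variance == pytest.approx(0.9, rel=0.05)

    def test_reproducible_under_fixed_seed(self):
        m1 = pp.GroupMoments("cases", 0.5, 1.0)
        m0 = pp.GroupMoments("noncases", 0.0, 1.0)
        a = pp.simulate_scores(m1, m0, 100, 100, seed=4)
        b = pp.simulate_scores(m1, m0, 100, 100, seed=4)
        np.testing.assert_array_equal(a.values, b.values)


class TestFitLogistic:
    def test_null_scores_give_near_zero_slope(self):
        g = pp.GroupMoments("cases", 0.0, 1.0)
        fit = pp.fit_logistic(pp.simulate_scores(g, g, 20_000, 20_000, seed=9))
        assert abs(fit.beta) < 5 * fit.beta_se

    def test_reanchoring_noop_at_sample_fraction(self):
        m1 = pp.GroupMoments("cases", 0.5, 1.0)
        m0 = pp.GroupMoments("noncases", 0.0, 1.0)
        s = pp.simulate_scores(m1, m0, 1000, 3000, seed=1)
        plain = pp.fit_logistic(s)
        anchored = pp.fit_logistic(s, K_weighting=0.25)
        assert anchored.alpha == pytest.approx(plain.alpha)
        assert anchored.beta == pytest.approx(plain.beta)

    def test_consistent_with_closed_form(self):
        m1 = pp.GroupMoments("cases", 0.4, 1.0)
        m0 = pp.GroupMoments("noncases", 0.0, 1.0)
        K = 0.1
        s = pp.simulate_scores(m1, m0, 50_000, 50_000, seed=12)
        fit = pp.fit_logistic(s, K_weighting=K)
        curve = pp.closed_form_coefficients(m1, m0, K)
        assert fit.beta == pytest.approx(curve.beta, abs=3 * fit.beta_se)
        assert fit.alpha == pytest.approx(curve.alpha, abs=3 * fit.alpha_se)

    def test_perfect_separation_raises(self):
        values = np.concatenate([np.ones(50), -np.ones(50)])
        labels = values > 0
        with pytest.raises(ValueError, match="separation"):
            pp.fit_logistic(pp.ScoreSet(values, labels))

    def test_unlabelled_scores_rejected(self):
        with pytest.raises(ValueError, match="label"):
            pp.fit_logistic(pp.ScoreSet(np.arange(10.0)))


class TestWeightedLogitFit:
    def test_exact_for_equal_variances(self, cases_eq, noncases_eq):
        a, b = pp.weighted_logit_fit(cases_eq, noncases_eq, 0.1)
        c = pp.closed_form_coefficients(cases_eq, noncases_eq, 0.1)
        assert b == pytest.approx(c.beta, abs=1e-6)
        assert a == pytest.approx(c.alpha, abs=1e-6)

    def test_matches_closed_form_for_unequal_variances(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g1, g0, K = random_moments(rng)
            a, b = pp.weighted_logit_fit(g1, g0, K)
            c = pp.closed_form_coefficients(g1, g0, K)
            assert b == pytest.approx(c.beta, rel=1e-3)
            assert a == pytest.approx(c.alpha, rel=1e-3, abs=1e-3)

    def test_constant_log_odds_gives_zero_slope(self):
        g1 = pp.GroupMoments("cases", 0.3, 1.0)
        g0 = pp.GroupMoments("noncases", 0.3, 1.0)
        a, b = pp.weighted_logit_fit(g1, g0, 0.2)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(np.log(0.25), abs=1e-10)

    def test_degenerate_grid_rejected(self, cases_eq, noncases_eq):
        with pytest.raises(ValueError, match="grid"):
            pp.weighted_logit_fit(cases_eq, noncases_eq, 0.1, n_grid=2)


class TestCompositeScoreWeights:
    @staticmethod
    def _simulated(seed, b_prs=1.0, b_var=0.8, n=30_000):
        rng = np.random.default_rng(seed)
        prs = rng.normal(size=n)
        var = rng.binomial(2, 0.15, size=n).astype(float)
        logit_p = -1.0 + b_prs * prs + b_var * var
        y = rng.random(n) < 1 / (1 + np.exp(-logit_p))
        return pp.ScoreSet(prs, y), var

    def test_recovers_true_per_allele_log_odds(self):
        scores, var = self._simulated(31)
        w_prs, w_var = pp.composite_score_weights(scores, var)
        assert w_prs == pytest.approx(1.0, abs=0.08)
        assert w_var == pytest.approx(0.8, abs=0.08)

    def test_permuted_labels_give_null_weights(self):
        scores, var = self._simulated(32)
        rng = np.random.default_rng(0)
        shuffled = pp.ScoreSet(scores.values, rng.permutation(scores.labels))
        w_prs, w_var = pp.composite_score_weights(shuffled, var)
        assert abs(w_prs) < 0.05 and abs(w_var) < 0.1

    def test_constant_variant_score_unidentifiable(self):
        scores, var = self._simulated(33)
        with pytest.raises(ValueError, match="unidentifiable"):
            pp.composite_score_weights(scores, np.ones_like(var))


class TestValidate:
    def test_seeded_report_is_reproducible(self):
        cfg = pp.ors_like_scenario(800, 800, seed=5)
        r1 = pp.validate(cfg, 0.1)
        r2 = pp.validate(cfg, 0.1)
        np.testing.assert_array_equal(r1.p_genotype_sim, r2.p_genotype_sim)
        assert r1.max_discrepancy == r2.max_discrepancy

    def test_weighted_logit_agrees_with_closed_form_curve(self):
        cfg = pp.ors_like_scenario(800, 800, seed=5)
        report = pp.validate(cfg, 0.1)
        assert report.max_discrepancy["weighted_logit"] < 1e-6

    def test_score_sampling_discrepancy_shrinks_with_n(self):
        m1 = pp.GroupMoments("cases", 0.4, 1.0)
        m0 = pp.GroupMoments("noncases", 0.0, 1.0)
        curve = pp.closed_form_coefficients(m1, m0, 0.1)

        def max_disc(n, seed):
            s = pp.simulate_scores(m1, m0, n, n, seed=seed)
            fit = pp.fit_logistic(s, K_weighting=0.1)
            x = np.linspace(-4, 4, 81)
            from scipy.special import expit

            return np.max(np.abs(expit(fit.alpha + fit.beta * x)
                                 - expit(curve.alpha + curve.beta * x)))

        # root-n convergence of the Monte-Carlo discrepancy: average over
        # seeds so a single lucky small-sample draw cannot mask the trend
        seeds = range(6, 11)
        small = np.mean([max_disc(1_000, s) for s in seeds])
        large = np.mean([max_disc(64_000, s) for s in seeds])
        assert large < small / 2

    def test_oligogenic_scenario_shows_larger_deviation(
        self, paper_scale_report, ors_scale_report
    ):
        """Few strong SNPs deviate more from normality than many weak ones."""
        assert (
            ors_scale_report.max_discrepancy["genotype_sim"]
            > paper_scale_report.max_discrepancy["genotype_sim"]
        )

    def test_summary_mentions_every_procedure(self, ors_scale_report):
        text = ors_scale_report.summary()
        for key in ("genotype_sim", "score_sim", "weighted_logit"):
            assert key in text
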