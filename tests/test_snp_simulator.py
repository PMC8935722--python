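import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chisquare

import grsforge as gf
from grsforge.snp_simulator import (
    Term,
    TrueModel,
    as_null,
    build_true_model,
    calibrate_intercept,
    draw_mafs,
    linear_predictor,
    normal_iqr,
    or_per_iqr_to_beta,
    simulate_environment,
    simulate_genotypes,
    simulate_outcome,
)


class TestMafDraws:
    def test_degenerate_range_gives_constant_mafs(self):
        d = gf.scenario1_design(1.5, 4, 500, maf_range=(0.3, 0.3))
        mafs = draw_mafs(d, np.random.default_rng(0))
        assert np.allclose(mafs, 0.3)

    def test_support_and_mean(self, rng):
        d = gf.scenario1_design(1.5, 99_994, 500)  # 10^5 SNPs worth of draws
        mafs = draw_mafs(d, rng)
        assert mafs.min() >= 0.15 and mafs.max() <= 0.45
        se = (0.45 - 0.15) / np.sqrt(12) / np.sqrt(len(mafs))
        assert abs(mafs.mean() - 0.30) < 3 * se


class TestGenotypeSampling:
    def test_zero_maf_gives_all_reference(self, rng):
        g = simulate_genotypes([0.0, 0.0], 50, rng)
        assert (g.values == 0).all()

    def test_marginal_distribution_matches_binomial(self, rng):
        n = 100_000
        g = simulate_genotypes([0.3], n, rng)
        counts = np.bincount(g.values[:, 0], minlength=3)
        expected = np.array([0.49, 0.42, 0.09]) * n
        se = np.sqrt(expected * (1 - expected / n))
        assert (np.abs(counts - expected) < 3 * se).all()
        # chi-square goodness of fit at alpha = 0.001
        assert chisquare(counts, expected).pvalue > 0.001

    def test_columns_independent(self, rng):
        g = simulate_genotypes([0.3, 0.4, 0.2], 100_000, rng)
        corr = np.corrcoef(g.values.T)
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off_diag).max() < 3 / np.sqrt(100_000)


class TestEnvironment:
    def test_only_gxe_scenario_has_environment(self, rng):
        d = gf.scenario1_design(1.5, 4, 100)
        with pytest.raises(ValueError):
            simulate_environment(d, 10, rng)

    @pytest.mark.parametrize("rho", [0.5, 0.9])
    def test_moments_match_design(self, rho, rng):
        d = gf.scenario3_design(1.5, 2, rho)
        env = simulate_environment(d, 100_000, rng)
        assert env.shape == (100_000, 2)
        assert np.allclose(env.mean(axis=0), 20.0, atol=0.05)
        assert np.allclose(env.var(axis=0), 10.0, rtol=0.03)
        r = np.corrcoef(env.T)[0, 1]
        se = (1 - rho ** 2) / np.sqrt(100_000)
        assert abs(r - rho) < 4 * se


class TestIqrScaling:
    def test_or_one_gives_zero_coefficient(self):
        assert or_per_iqr_to_beta(1.0, 10.0) == 0.0

    def test_theoretical_iqr_value(self):
        # 2 * Phi^{-1}(0.75) * sqrt(10) = 1.34898 * 3.16228
        assert normal_iqr(10.0) == pytest.approx(4.26585, abs=1e-4)

    def test_coefficient_for_or_1p2(self):
        assert or_per_iqr_to_beta(1.2, 10.0) == pytest.approx(np.log(1.2) / 4.26585, abs=1e-5)


class TestLinearPredictor:
    def test_all_reference_genotypes_leave_only_intercept(self):
        model = TrueModel(-0.7, [Term("snp_d", 0.5, snps=(0,))])
        eta = linear_predictor(model, np.zeros((4, 3), dtype=int))
        assert np.allclose(eta, -0.7)

    def test_marginal_scenario_adds_per_snp_effects(self):
        beta = np.log(1.5)
        model = TrueModel(-1.0, [Term("snp_d", beta, snps=(i,)) for i in range(6)])
        eta = linear_predictor(model, np.ones((2, 6), dtype=int))
        assert np.allclose(eta, -1.0 + 6 * beta)

    def test_interaction_term_needs_both_snps(self):
        model = TrueModel(0.0, [Term("snp_d_product", 1.0, snps=(3, 4))])
        g = np.zeros((3, 6), dtype=int)
        g[1, 3] = 1          # only one interacting SNP carries the risk allele
        g[2, 3] = g[2, 4] = 2  # both do
        eta = linear_predictor(model, g)
        assert np.allclose(eta, [0.0, 0.0, 1.0])

    def test_environment_required_for_gxe_terms(self):
        model = TrueModel(0.0, [Term("env", 0.1, env=0)])
        with pytest.raises(ValueError, match="environment"):
            linear_predictor(model, np.zeros((2, 2), dtype=int))


class TestIntercentCalibration:
    def test_null_model_is_exactly_zero(self):
        assert calibrate_intercept(gf.null_design(10, 100)) == 0.0

    def test_strong_marginal_design_balances_cases(self):
        d = gf.scenario1_design(1.8, 4, 1000, seed=5)
        b0 = calibrate_intercept(d, n_calibration=100_000)
        assert b0 < 0  # all effects are risk-increasing
        model = build_true_model(d, calibrate=False)
        model.intercept = b0
        rng = np.random.default_rng(99)
        # mean case fraction over replicate-style draws (fresh MAFs each time)
        fractions = []
        for _ in range(20):
            g = simulate_genotypes(draw_mafs(d, rng), 5000, rng)
            fractions.append(simulate_outcome(model, g, rng=rng).case_fraction)
        assert 0.48 <= np.mean(fractions) <= 0.52

    def test_case_fraction_increases_with_intercept(self):
        d = gf.scenario1_design(1.5, 4, 500, seed=2)
        model = build_true_model(d, calibrate=False)
        rng = np.random.default_rng(0)
        g = simulate_genotypes(draw_mafs(d, rng), 5000, rng)
        fractions = []
        for b0 in (-2.0, 0.0, 2.0):
            model.intercept = b0
            fractions.append(expit(linear_predictor(model, g)).mean())
        assert fractions[0] < fractions[1] < fractions[2]


class TestOutcome:
    def test_saturated_intercept_gives_all_cases(self, rng):
        model = TrueModel(50.0, [])
        y = simulate_outcome(model, np.zeros((200, 2), dtype=int), rng=rng)
        assert y.values.sum() == 200

    def test_stratified_case_rate_matches_risk(self, rng):
        beta = np.log(3.0)
        model = TrueModel(-0.5, [Term("snp_d", beta, snps=(0,))])
        g = simulate_genotypes([0.4], 100_000, rng)
        y = simulate_outcome(model, g, rng=rng).values
        for dom in (0, 1):
            mask = (g.values[:, 0] != 0) == dom
            p = expit(-0.5 + beta * dom)
            se = np.sqrt(p * (1 - p) / mask.sum())
            assert abs(y[mask].mean() - p) < 3 * se


class TestReplicates:
    def test_equal_seeds_reproduce_datasets(self):
        d = gf.scenario1_design(1.5, 4, 100, seed=42, n_replicates=3)
        a = gf.generate_replicates(d)
        b = gf.generate_replicates(d)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.genotypes.values, rb.genotypes.values)
            assert np.array_equal(ra.outcome.values, rb.outcome.values)
            assert np.allclose(ra.mafs, rb.mafs)

    def test_scenario_dimensions(self):
        d1 = gf.scenario1_design(1.2, 4, 100, seed=0, n_replicates=2)
        for ds in gf.generate_replicates(d1):
            assert ds.genotypes.n_snps == 10
            assert ds.environment is None
        d3 = gf.scenario3_design(1.5, 5, 0.5, sample_size=100, seed=0, n_replicates=2)
        for ds in gf.generate_replicates(d3):
            assert ds.genotypes.n_snps == 50
            assert ds.environment.shape == (100, 2)

    def test_replicates_redraw_mafs(self):
        d = gf.scenario1_design(1.5, 4, 50, seed=1, n_replicates=2)
        a, b = gf.generate_replicates(d)
        assert not np.allclose(a.mafs, b.mafs)


class TestScenarioSweeps:
    @pytest.mark.parametrize("scenario,count", [("marginal", 27), ("gene_gene", 45), ("gxe", 20)])
    def test_setting_counts(self, scenario, count):
        settings = gf.enumerate_scenario_settings(scenario)
        assert len(settings) == count
        assert len({
            (s.snp_or, s.n_noise, s.sample_size, s.interaction_or, s.interaction_pair,
             s.gxe_or, s.gxe_index, s.env_correlation) for s in settings
        }) == count


class TestTrueModelPredictions:
    def test_equal_effects_give_seven_distinct_risks(self):
        d = gf.scenario1_design(1.5, 0, 100, seed=0)
        model = build_true_model(d, calibrate=False)
        model.intercept = -1.0
        patterns = np.array(np.meshgrid(*[[0, 1, 2]] * 6)).reshape(6, -1).T
        risks = gf.true_model_predict(model, patterns)
        assert len(np.unique(np.round(risks, 12))) == 7

    def test_risks_increase_with_dominant_count(self):
        beta = np.log(1.8)
        model = TrueModel(-2.0, [Term("snp_d", beta, snps=(i,)) for i in range(6)])
        g = np.zeros((7, 6), dtype=int)
        for k in range(7):
            g[k, :k] = 1
        risks = gf.true_model_predict(model, g)
        assert (np.diff(risks) > 0).all()

    def test_null_model_predicts_half(self):
        model = TrueModel(0.0, [])
        assert np.allclose(gf.true_model_predict(model, np.zeros((3, 2), dtype=int)), 0.5)


def test_as_null_zeroes_all_effects():
    d = as_null(gf.scenario3_design(2.4, 5, 0.9))
    model = build_true_model(d)
    assert model.intercept == 0.0
    assert all(t.beta == 0.0 for t in model.terms)
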