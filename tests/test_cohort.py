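import numpy as np
import pytest
from scipy import stats

import pblev
from pblev.architectures import LevSpec, ParameterError, VariantPanel
from pblev.cohort import (
    DegenerateScoreError,
    TraitModel,
    assign_cases_liability,
    assign_cases_logit,
    calibrate_logit_intercept,
    carrier_case_risk,
    compute_pb,
    compute_pgs,
    map_logit_to_liability_score,
    simulate_cohort,
    simulate_genotypes,
    simulate_lev_genotype,
)


def mini_panel(mafs):
    mafs = np.asarray(mafs, dtype=float)
    ids = np.array([f"v{i}" for i in range(len(mafs))], dtype=object)
    return VariantPanel(ids, mafs, np.zeros_like(mafs))


class TestSimulateGenotypes:
    def test_binomial_mean_at_half(self, rng):
        blk = simulate_genotypes(mini_panel([0.5]), 100_000, rng)
        se = np.sqrt(2 * 0.5 * 0.5 / 100_000)
        assert abs(blk.counts.mean() - 1.0) < 3 * se

    def test_columns_independent(self, rng):
        blk = simulate_genotypes(mini_panel([0.3, 0.3]), 100_000, rng)
        r = np.corrcoef(blk.counts[:, 0], blk.counts[:, 1])[0, 1]
        assert abs(r) < 0.01

    def test_standardized_block_moments(self, rng):
        blk = simulate_genotypes(mini_panel([0.1, 0.25, 0.5]), 20_000, rng)
        z = blk.standardized("empirical")
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)
        zp = blk.standardized("population")
        assert np.all(np.abs(zp.mean(axis=0)) < 0.05)
        assert np.all(np.abs(zp.std(axis=0) - 1) < 0.05)

    def test_monomorphic_column_flagged_or_resampled(self):
        # tiny n at the lowest grid frequency: column is either rescued by
        # the single resample or flagged monomorphic, never silent
        rng = np.random.default_rng(0)
        blk = simulate_genotypes(mini_panel([1e-4]), 2, rng)
        col_constant = (blk.counts[:, 0] == blk.counts[0, 0]).all()
        assert blk.monomorphic[0] == col_constant

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ParameterError):
            simulate_genotypes(mini_panel([0.1]), 1, rng)


class TestSimulateLevGenotype:
    def test_zero_frequency_all_zero(self, rng):
        g = simulate_lev_genotype(LevSpec(0.0, 0.0, 0.0), 100, rng)
        assert not g.any()

    def test_carrier_fraction_hwe(self, rng):
        f = 0.005
        g = simulate_lev_genotype(LevSpec.from_h2(0.01, f), 1_000_000, rng)
        expected = 1 - (1 - f) ** 2
        se = np.sqrt(expected * (1 - expected) / 1_000_000)
        assert abs((g >= 1).mean() - expected) < 3 * se

    def test_dprime_one_haplotype_structure(self, rng):
        f, f_partner, n = 0.001, 0.3, 1_000_000
        hap_a = rng.random(n) < f_partner
        hap_b = rng.random(n) < f_partner
        lev = LevSpec.from_h2(0.01, f)
        g = simulate_lev_genotype(
            lev, n, rng, dependence="dprime_one",
            partner_haplotypes=(hap_a, hap_b), partner_freq=f_partner,
        )
        assert g.sum() > 0
        # D' = 1: LEV alleles only ever ride on partner-allele haplotypes;
        # carriers with g==2 must have both partner haplotypes
        assert np.all(hap_a[g == 2] & hap_b[g == 2])
        assert np.all((hap_a | hap_b)[g >= 1])
        # empirical D' estimate from genotype frequencies
        p_lev = g.mean() / 2
        assert p_lev == pytest.approx(f, rel=0.2)

    def test_dprime_one_frequency_constraint(self, rng):
        lev = LevSpec.from_h2(0.01, 0.4)
        with pytest.raises(ParameterError):
            simulate_lev_genotype(
                lev, 10, rng, dependence="dprime_one",
                partner_haplotypes=(np.zeros(10, bool), np.zeros(10, bool)),
                partner_freq=0.2,
            )


class TestScores:
    def test_pb_zero_effects(self, panel, rng):
        blk = simulate_genotypes(panel, 100, rng)
        eff = pblev.draw_effect_sizes(panel, pblev.ArchitectureSpec(), 0.0, rng)
        assert not compute_pb(blk.standardized(), eff).any()

    def test_pb_single_variant_identity(self, rng):
        p = mini_panel([0.3])
        blk = simulate_genotypes(p, 1000, rng)
        eff = pblev.draw_effect_sizes(p, pblev.ArchitectureSpec(), 0.25, rng)
        z = blk.standardized()
        pb = compute_pb(z, eff)
        assert np.allclose(pb, z[:, 0] * eff.beta_pb[0])

    def test_pb_variance_bookkeeping(self, panel2000, rng):
        n = 20_000
        blk = simulate_genotypes(panel2000, n, rng)
        eff = pblev.draw_effect_sizes(panel2000, pblev.ArchitectureSpec(), 0.3, rng)
        pb = compute_pb(blk.standardized(), eff)
        # dominant uncertainty: chi-square fluctuation of sum(beta^2)
        mc_se = 0.3 * np.sqrt(2.0 / 2000)
        assert abs(pb.var() - 0.3) < 3 * mc_se

    def test_pgs_dimension_check(self, panel, rng):
        eff = pblev.draw_effect_sizes(panel, pblev.ArchitectureSpec(), 0.3, rng)
        with pytest.raises(ParameterError):
            compute_pb(np.zeros((10, 3)), eff)

    def test_degenerate_score_raises(self, rng):
        p = mini_panel([0.3, 0.4])
        blk = simulate_genotypes(p, 50, rng)
        eff = pblev.draw_effect_sizes(p, pblev.ArchitectureSpec(), 0.0, rng)
        w = pblev.make_pgs_weights(eff, 0.0)
        with pytest.raises(DegenerateScoreError):
            compute_pgs(blk.standardized(), w)


class TestAttenuation:
    """corr(PGS, PB) ~ 1-pi0 (weighted_nulls) or sqrt(1-pi0) (dropped)."""

    @pytest.mark.parametrize(
        "pi0,mode,target",
        [
            (0.9, "weighted_nulls", 0.10),
            (0.9, "dropped_causals", np.sqrt(0.10)),
            (0.5, "weighted_nulls", 0.50),
            (0.5, "dropped_causals", np.sqrt(0.50)),
        ],
    )
    def test_expected_correlation(self, panel2000, pi0, mode, target):
        trait = TraitModel(
            h2_pb=0.3, lev=LevSpec.from_h2(0.01, 0.05), prevalence=0.05,
            pi0=pi0, pgs_mode=mode,
        )
        corrs = [
            np.corrcoef(
                (c := simulate_cohort(trait, pblev.ArchitectureSpec(), panel2000,
                                      30_000, seed=100 + r)).pgs, c.pb_true
            )[0, 1]
            for r in range(6)
        ]
        se = np.std(corrs, ddof=1) / np.sqrt(len(corrs))
        assert abs(np.mean(corrs) - target) < max(3 * se, 0.02)


class TestLiabilityModel:
    def test_threshold_values(self):
        t_half = TraitModel(0.0, LevSpec(0.1, 0.0, 0.0), 0.5)
        assert t_half.threshold == pytest.approx(0.0, abs=1e-12)
        t_one = TraitModel(0.0, LevSpec(0.1, 0.0, 0.0), 0.01)
        assert t_one.threshold == pytest.approx(2.3263, abs=1e-4)

    def test_residual_only_case_fraction(self, rng):
        trait = TraitModel(0.0, LevSpec(0.1, 0.0, 0.0), 0.01)
        n = 1_000_000
        pb = np.zeros(n)
        g = np.zeros(n, dtype=np.int8)
        _, t, case, _ = assign_cases_liability(pb, g, trait.lev, trait, rng)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(case.mean() - 0.01) < 3 * se

    def test_calibrated_threshold_conserves_prevalence(self):
        trait = TraitModel(0.3, LevSpec.from_h2(0.03, 0.005), 0.01)
        # analytic case rate at the calibrated threshold
        f, beta = trait.lev.freq, trait.lev.beta_lev
        pg = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        rate = sum(
            pg[g] * stats.norm.sf((trait.threshold - beta * g) / np.sqrt(1 - 0.03))
            for g in range(3)
        )
        assert rate == pytest.approx(0.01, rel=1e-8)
        # nominal threshold would overshoot
        assert trait.threshold > trait.nominal_threshold

    def test_nonpositive_residual_variance_rejected(self):
        with pytest.raises(ParameterError):
            TraitModel(0.6, LevSpec.from_h2(0.3, 0.1), 0.01, interaction_h2=0.2)

    def test_carrier_risk_oracle(self, panel):
        """Simulated P(case | G_LEV=g) matches Phi((g*beta-t)/sqrt(1-h2_lev)).

        Averaged over replicates because the realized PB variance of a
        finite causal panel fluctuates around h2_pb (rel. sd sqrt(2/n_pb)),
        which shifts single-replicate conditional rates; the empirical
        across-replicate se captures both noise sources.
        """
        trait = TraitModel(0.3, LevSpec.from_h2(0.05, 0.05), 0.02)
        reps = [
            simulate_cohort(trait, pblev.ArchitectureSpec(), panel, 150_000,
                            n_pb=500, seed=77 + r)
            for r in range(6)
        ]
        for g in (0, 1):
            rates = np.array(
                [c.case[c.lev_genotype == g].mean() for c in reps]
            )
            expected = carrier_case_risk(trait, g)
            se = rates.std(ddof=1) / np.sqrt(len(rates))
            assert abs(rates.mean() - expected) < 3.5 * se

    def test_cases_have_higher_pb(self, panel, low_trait):
        c = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 50_000,
                            n_pb=300, seed=5)
        assert c.pb_true[c.case].mean() > c.pb_true[~c.case].mean()

    def test_liability_variance_normalized(self, panel, low_trait):
        c = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 50_000,
                            n_pb=300, seed=6)
        assert c.liability.var() == pytest.approx(1.0, abs=0.03)


class TestLogitModel:
    def test_degenerate_intercept_closed_form(self):
        trait = TraitModel(0.0, LevSpec(0.1, 0.0, 0.0), 0.01, liability_model="logit")
        u0 = calibrate_logit_intercept(trait)
        assert u0 == pytest.approx(np.log(0.01 / 0.99), abs=1e-6)

    def test_symmetric_intercept_is_zero(self):
        trait = TraitModel(0.3, LevSpec(0.1, 0.0, 0.0), 0.5, liability_model="logit")
        assert calibrate_logit_intercept(trait) == pytest.approx(0.0, abs=1e-6)

    def test_intercept_against_mc_oracle(self):
        trait = TraitModel(0.3, LevSpec(0.1, 0.0, 0.0), 0.05, liability_model="logit")
        u0 = calibrate_logit_intercept(trait)
        rng = np.random.default_rng(3)
        x = rng.normal(0, np.sqrt(0.3), 2_000_000)
        ep = (1 / (1 + np.exp(-(x + u0)))).mean()
        assert ep == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 2e6) + 1e-4)

    def test_assign_cases_logit_values(self, rng):
        p, _ = assign_cases_logit(np.zeros(3), 0.0, 1.0, rng)
        assert np.allclose(p, 0.5)
        p2, _ = assign_cases_logit(np.array([np.log(0.01 / 0.99)]), 0.0, 1.0, rng)
        assert p2[0] == pytest.approx(0.01, rel=1e-10)

    def test_calibrated_case_rate(self, panel):
        trait = TraitModel(0.3, LevSpec.from_h2(0.02, 0.01), 0.02,
                           liability_model="logit")
        c = simulate_cohort(trait, pblev.ArchitectureSpec(), panel, 300_000,
                            n_pb=300, seed=21)
        se = np.sqrt(0.02 * 0.98 / 300_000)
        assert abs(c.case.mean() - 0.02) < 3.5 * se

    def test_map_logit_to_liability_round_trip(self):
        trait = TraitModel(0.3, LevSpec.from_h2(0.03, 0.005), 0.01)
        u0 = -4.2
        x = np.linspace(-3, 3, 101)
        x_liab = map_logit_to_liability_score(x, u0, 1.0, trait)
        # composing with the liability risk function reproduces the logit risk
        from scipy.special import expit

        p_logit = expit(x + u0)
        sd = np.sqrt(1 - trait.h2_pb - trait.lev.h2_lev)
        p_liab = stats.norm.sf((trait.threshold - x_liab) / sd)
        assert np.allclose(p_liab, p_logit, atol=1e-10)
        assert np.all(np.diff(x_liab) > 0)  # monotone


class TestCohortEngine:
    def test_fused_and_materialized_paths_agree(self, panel, low_trait):
        a = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 5000,
                            n_pb=200, seed=13)
        b = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 5000,
                            n_pb=200, seed=13, keep_dosages=True)
        assert np.array_equal(a.lev_genotype, b.lev_genotype)
        assert np.allclose(a.pb_true, b.pb_true, atol=1e-9)
        assert np.allclose(a.pgs, b.pgs, atol=1e-7)
        assert np.array_equal(a.case, b.case)
        assert b.dosages is not None and b.dosages.shape == (5000, 200)

    def test_reproducible_given_seed(self, panel, low_trait):
        a = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 2000, n_pb=100, seed=4)
        b = simulate_cohort(low_trait, pblev.ArchitectureSpec(), panel, 2000, n_pb=100, seed=4)
        assert np.array_equal(a.pgs, b.pgs)
        assert np.array_equal(a.case, b.case)

    def test_switches_off_reproduce_baseline_bitwise(self, panel):
        base = TraitModel(0.3, LevSpec.from_h2(0.01, 0.01), 0.01)
        off = TraitModel(0.3, LevSpec.from_h2(0.01, 0.01), 0.01,
                         subtype_lambda=0.8, subtype_minor_proportion=0.0,
                         interaction_h2=0.0, dependence="independent")
        a = simulate_cohort(base, pblev.ArchitectureSpec(), panel, 3000, n_pb=100, seed=9)
        b = simulate_cohort(off, pblev.ArchitectureSpec(), panel, 3000, n_pb=100, seed=9)
        assert np.array_equal(a.liability, b.liability)
        assert np.array_equal(a.case, b.case)

    def test_subtype_changes_liability(self, panel):
        on = TraitModel(0.3, LevSpec.from_h2(0.01, 0.01), 0.01,
                        subtype_lambda=1.0, subtype_minor_proportion=0.5)
        base = TraitModel(0.3, LevSpec.from_h2(0.01, 0.01), 0.01)
        a = simulate_cohort(base, pblev.ArchitectureSpec(), panel, 3000, n_pb=100, seed=9)
        b = simulate_cohort(on, pblev.ArchitectureSpec(), panel, 3000, n_pb=100, seed=9)
        assert not np.array_equal(a.liability, b.liability)

    def test_interaction_variance_contribution(self, panel):
        # the product term contributes its nominal interaction_h2; total
        # var(L) carries the finite-panel Sigma beta^2 fluctuation plus a
        # small unorthogonalized covariance with the top variant's main
        # effect, so the band is wider than for the additive model
        on = TraitModel(0.3, LevSpec.from_h2(0.02, 0.05), 0.01, interaction_h2=0.04)
        c = simulate_cohort(on, pblev.ArchitectureSpec(), panel, 50_000, n_pb=200, seed=2)
        assert c.liability.var() == pytest.approx(1.0, abs=0.09)

    def test_dprime_one_cohort_runs(self, panel):
        tr = TraitModel(0.3, LevSpec.from_h2(0.01, 0.001), 0.01, dependence="dprime_one")
        c = simulate_cohort(tr, pblev.ArchitectureSpec(), panel, 20_000, n_pb=200, seed=3)
        assert 0 < c.lev_genotype.sum() < 200
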