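"""Hierarchical Bayesian logistic model: log-posterior oracle, MCMC recovery,
HPDI and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.stats import norm

from isorisk import (
    PosteriorDraws,
    RiskModelSpec,
    SimulationSpec,
    build_risk_model,
    effective_sample_size,
    hpdi,
    r_hat,
    sample_posterior,
    simulate_cohort,
    summarize,
)
from isorisk.codebook import CohortTable
from isorisk.simulate import TraitSpec


def _toy_model():
    y = np.array([1.0, 0.0, 1.0])
    x1 = np.array([-1.0, 0.0, 1.0])  # z-scored 3-point trait
    x2 = np.array([-1.0, 0.0, 1.0])
    x3 = np.array([0.0, 1.0, 0.0])
    return RiskModelSpec(y=y, risk=x1, age=x2, sex=x3)


class TestLogPosterior:
    def test_all_zero_parameters_give_half_probability(self):
        m = _toy_model()
        # at alpha = betas = 0 every participant has p = 0.5, so the
        # likelihood part equals n * log(0.5)
        lp = m.log_posterior([0.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        priors = (
            4 * norm.logpdf(0.0)  # alpha, mu, agebeta, sexbeta
            + norm.logpdf(0.0, 0.0, 1.0)  # risktrait | mu, sigma
            + (0.5 * np.log(2 / np.pi) - 0.5)  # HalfNormal(1) at sigma = 1
        )
        assert abs(lp - (3 * np.log(0.5) + priors)) < 1e-10

    def test_hand_summed_toy_log_posterior(self):
        m = _toy_model()
        alpha, beta, mu, sigma, agebeta, sexbeta = 0.1, 0.2, 0.0, 1.0, 0.0, 0.0
        eta = alpha + beta * m.risk + agebeta * m.age + sexbeta * m.sex
        p = 1 / (1 + np.exp(-eta))
        loglik = sum(np.log(p[i]) if m.y[i] else np.log(1 - p[i]) for i in range(3))
        priors = (
            norm.logpdf(alpha)
            + norm.logpdf(beta, mu, sigma)
            + norm.logpdf(mu)
            + (0.5 * np.log(2 / np.pi) - 0.5 * sigma**2)
            + norm.logpdf(agebeta)
            + norm.logpdf(sexbeta)
        )
        got = m.log_posterior([alpha, beta, mu, sigma, agebeta, sexbeta])
        assert abs(got - (loglik + priors)) < 1e-10

    def test_nonpositive_sigma_outside_support(self):
        m = _toy_model()
        assert m.log_posterior([0, 0, 0, 0.0, 0, 0]) == -np.inf
        assert m.log_posterior([0, 0, 0, -1.0, 0, 0]) == -np.inf

    def test_sampling_space_matches_natural_space(self):
        # non-centered/log-sigma density must equal the natural one plus the
        # Jacobian of the reparameterization
        m = _toy_model()
        alpha, z, mu, ls, ab, sb = 0.3, -0.7, 0.2, -0.4, 0.1, -0.2
        sigma = np.exp(ls)
        beta = mu + sigma * z
        natural = m.log_posterior([alpha, beta, mu, sigma, ab, sb])
        # change of variables (beta, sigma) -> (z, log_sigma) has Jacobian
        # determinant sigma^2, so the densities differ by 2*log(sigma)
        expected = natural + 2 * ls
        got = float(m._logp_sampling(np.array([[alpha, z, mu, ls, ab, sb]]))[0])
        assert abs(got - expected) < 1e-10

    def test_map_gradient_matches_finite_differences(self):
        m = _toy_model()
        theta = np.array([0.2, -0.3, 0.1, -0.2, 0.4, -0.1])
        f0, g = m._neg_logp_grad(theta)
        num = optimize.approx_fprime(theta, lambda t: m._neg_logp_grad(t)[0], 1e-6)
        assert np.abs(g - num).max() < 1e-4


class TestBuildRiskModel:
    def test_rejects_nonbinary_target(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="binary"):
            build_risk_model(table.zscored(), "risk_trait", "age")

    def test_rejects_unstandardized_trait(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="z-score"):
            build_risk_model(table, "risk_trait", "loneliness")

    def test_rejects_missing_trait_values(self, small_cohort):
        table, _ = small_cohort
        t = table.zscored()
        t.data.loc[0, "risk_trait"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_risk_model(t, "risk_trait", "loneliness")


class TestSamplePosterior:
    def test_same_seed_identical_draws(self, small_model):
        a = sample_posterior(small_model, chains=2, draws=200, warmup=200, seed=5)
        b = sample_posterior(small_model, chains=2, draws=200, warmup=200, seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_posterior_mean_matches_mle_oracle(self, small_model):
        # the priors are weak at n = 2,000, so the posterior mean of the
        # trait coefficient must sit close to an independent maximum-
        # likelihood fit of the same logistic regression
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([small_model.risk, small_model.age,
                                             small_model.sex]))
        mle_beta = sm.Logit(small_model.y, X).fit(disp=0).params[1]
        d = sample_posterior(small_model, chains=2, draws=1000, warmup=500, seed=3)
        s = summarize(d)
        assert abs(s["risktrait"].mean - mle_beta) < 0.1
        assert abs(s["risktrait"].mean - 0.5) < 0.15  # generating truth

    def test_null_trait_hpdi_covers_zero(self):
        hits = 0
        for i in range(30):
            spec = SimulationSpec(
                n_participants=1000,
                trait_specs=[TraitSpec("risk_trait", "continuous", "lifestyle")],
                true_beta={"risk_trait": 0.0},
                true_age_beta=0.2,
                true_sex_beta=-0.3,
                seed=500 + i,
            )
            table, _ = simulate_cohort(spec)
            m = build_risk_model(table.zscored(), "risk_trait", "loneliness")
            s = summarize(sample_posterior(m, chains=2, draws=500, warmup=500, seed=600 + i))
            hits += s["risktrait"].hpdi_low <= 0.0 <= s["risktrait"].hpdi_high
        assert hits >= 26  # >= 85% of replicates

    def test_age_confounded_trait_shows_no_direct_effect(self):
        # trait correlated with age but conditionally independent of the
        # target given age: its coefficient should straddle zero
        from scipy.special import expit

        hits = 0
        for i in range(30):
            g = np.random.default_rng(900 + i)
            n = 1000
            age = g.uniform(40, 70, n)
            z_age = (age - age.mean()) / age.std(ddof=1)
            trait = 0.8 * z_age + 0.6 * g.standard_normal(n)
            sex = g.binomial(1, 0.5, n).astype(float)
            y = g.binomial(1, expit(0.5 * z_age)).astype(float)
            df = pd.DataFrame(
                {
                    "participant_id": np.arange(n),
                    "loneliness": y,
                    "age": age,
                    "sex": sex,
                    "trait": trait,
                }
            )
            table = CohortTable(
                df,
                {"loneliness": "target", "age": "confound", "sex": "confound",
                 "trait": "risk_trait"},
            )
            m = build_risk_model(table.zscored(["trait"]), "trait", "loneliness")
            s = summarize(sample_posterior(m, chains=2, draws=500, warmup=500, seed=950 + i))
            hits += s["risktrait"].hpdi_low <= 0.0 <= s["risktrait"].hpdi_high
        assert hits >= 26

    def test_posterior_means_increase_with_generating_beta(self):
        means = []
        for beta in (0.0, 0.25, 0.5):
            spec = SimulationSpec(
                n_participants=2000,
                trait_specs=[TraitSpec("risk_trait", "continuous", "lifestyle")],
                true_beta={"risk_trait": beta},
                seed=21,  # matched seeds: same participants, same noise draws
            )
            table, _ = simulate_cohort(spec)
            m = build_risk_model(table.zscored(), "risk_trait", "loneliness")
            s = summarize(sample_posterior(m, chains=2, draws=500, warmup=500, seed=22))
            means.append(s["risktrait"].mean)
        assert means[0] < means[1] < means[2]

    def test_prior_only_model_reproduces_priors(self):
        empty = RiskModelSpec(
            y=np.empty(0), risk=np.empty(0), age=np.empty(0), sex=np.empty(0)
        )
        d = sample_posterior(empty, chains=4, draws=5000, warmup=4000, seed=8)
        s = summarize(d)
        for name in ("alpha", "agebeta", "sexbeta"):
            assert abs(s[name].mean) < 0.1
        assert abs(s["sigma_risk"].mean - np.sqrt(2 / np.pi)) < 0.05

    def test_zero_draws_rejected(self, small_model):
        with pytest.raises(ValueError, match="draws"):
            sample_posterior(small_model, chains=1, draws=0, seed=1)


class TestHPDI:
    def test_degenerate_draws_collapse(self):
        assert hpdi([3.0] * 50, 0.9) == (3.0, 3.0)

    def test_interval_contains_required_mass(self, rng):
        x = rng.standard_normal(5000)
        lo, hi = hpdi(x, 0.9)
        assert ((x >= lo) & (x <= hi)).sum() >= int(np.ceil(0.9 * 5000))

    def test_matches_arviz_hdi(self, rng):
        # both estimators target the same interval; each carries its own
        # window-slide noise (~0.03-0.08 for skewed shapes), hence the bands
        import arviz as az

        x = rng.standard_normal(50000)
        lo, hi = hpdi(x, 0.9)
        a_lo, a_hi = az.hdi(x, hdi_prob=0.9)
        assert abs(lo - a_lo) < 0.06 and abs(hi - a_hi) < 0.06
        g = rng.gamma(2.0, size=50000)
        lo, hi = hpdi(g, 0.9)
        a_lo, a_hi = az.hdi(g, hdi_prob=0.9)
        assert abs(lo - a_lo) < 0.12 and abs(hi - a_hi) < 0.12

    def test_validation(self):
        with pytest.raises(ValueError, match="10 draws"):
            hpdi([1.0] * 5, 0.9)
        with pytest.raises(ValueError, match="mass"):
            hpdi(list(range(100)), 1.5)


class TestDiagnostics:
    def test_rhat_near_one_for_well_mixed_chains(self, rng):
        assert r_hat(rng.standard_normal((4, 1000))) < 1.01

    def test_rhat_large_for_separated_chains(self, rng):
        chains = rng.standard_normal((2, 1000)) + np.array([[0.0], [5.0]])
        got = r_hat(chains)
        # classic split-Rhat formula on the same chains as an oracle
        split = chains.reshape(4, 500)
        w = split.var(axis=1, ddof=1).mean()
        b = 500 * split.mean(axis=1).var(ddof=1)
        classic = np.sqrt((499 / 500 * w + b / 500) / w)
        assert classic > 1.5 and got > 1.5

    def test_constant_chains_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_hat(np.ones((4, 100)))

    def test_ess_close_to_nominal_for_iid(self, rng):
        ess = effective_sample_size(rng.standard_normal((4, 1000)))
        assert abs(ess - 4000) < 0.2 * 4000

    def test_ess_collapses_for_autocorrelated_chain(self, rng):
        phi = 0.9
        n = 4000
        chains = np.empty((4, n))
        for c in range(4):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
            chains[c] = x
        # closed form: ESS/N = (1 - phi) / (1 + phi) ~= 5.3%
        assert effective_sample_size(chains) < 0.15 * chains.size

    def test_single_draw_per_chain_rejected(self):
        with pytest.raises(ValueError, match="draws"):
            effective_sample_size(np.ones((4, 1)))


class TestSummarize:
    def test_degenerate_draws_summary(self):
        d = PosteriorDraws(
            params={"alpha": np.full((2, 50), 2.5)}, seed=0, warmup=0, sampler="none"
        )
        s = summarize(d)
        assert s["alpha"].mean == 2.5
        assert (s["alpha"].hpdi_low, s["alpha"].hpdi_high) == (2.5, 2.5)

    def test_mean_inside_own_hpdi(self, small_model):
        s = summarize(sample_posterior(small_model, chains=2, draws=500, warmup=500, seed=13))
        for p in s.params.values():
            assert p.hpdi_low <= p.mean <= p.hpdi_high

    def test_flagged_run_carries_warning(self, rng):
        bad = rng.standard_normal((2, 500)) + np.array([[0.0], [5.0]])
        d = PosteriorDraws(params={"risktrait": bad}, seed=0, warmup=0, sampler="none")
        s = summarize(d)
        assert any("r_hat" in w for w in s.warnings)
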