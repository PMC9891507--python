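# Methods

`isorisk` estimates population-level associations between two binary measures
of social isolation — loneliness (subjective) and lack of social support
(objective) — and a battery of candidate risk traits for Alzheimer's disease
and related dementias (ADRD), as done in large aging cohorts such as the UK
Biobank and the Canadian Longitudinal Study on Aging.  Cohort microdata of
this kind cannot be redistributed, so the package pairs the analysis stack
with a synthetic cohort generator whose ground truth is known exactly; every
quantitative guarantee below is stated with respect to that generator.

## The association model

For each risk trait and each target, a separate hierarchical Bayesian
logistic regression is fitted:

    y_i ~ Bernoulli(p_i)
    logit(p_i) = alpha + x1_i * risktrait + x2_i * agebeta + x3_i * sexbeta

    alpha      ~ Normal(0, 1)
    risktrait  ~ Normal(mu_risk, sigma_risk)
    mu_risk    ~ Normal(0, 1)
    sigma_risk ~ HalfNormal(1)
    agebeta    ~ Normal(0, 1)
    sexbeta    ~ Normal(0, 1)

`x1` is the z-scored trait (sample SD, denominator n−1), `x2` z-scored age,
`x3` a 0/1 sex indicator.  Coefficients are therefore log-odds per 1 SD of
the trait.  Age is z-scored even though only risk traits strictly require it,
so that its Normal(0,1) prior is on a comparable scale.  The multilevel prior
on the single trait coefficient lets the prior scale adapt to the data; it is
kept exactly as written even though a fixed prior would behave almost
identically for a scalar coefficient.

**Parameterization.**  The joint density is unbounded in natural space
(sigma_risk → 0 with risktrait = mu_risk, the usual hierarchical funnel), so
sampling uses the non-centered, log-transformed coordinates
`risktrait = mu_risk + exp(log_sigma) * z`, in which the density is proper
and smooth.  The sampling-space density equals the natural one plus the
Jacobian term `2*log(sigma)` (verified by a unit test).

**Sampling.**  Posterior integration is MCMC via affine-invariant ensemble
sampling (emcee).  A "chain" is one independent ensemble of ≥ 2·dim+2
walkers, initialized as a seeded scatter (SD 0.3) around the posterior mode
found by L-BFGS with an analytic gradient.  Defaults: 4 chains for
exploration, 1 chain for a final solution; 1,000 retained draws and 1,000
warmup draws per chain.  Because warmup is counted in draws but the ensemble
advances in steps, each chain runs at least 100 warmup *steps* regardless of
the nominal warmup count — ensembles need a minimum number of moves to
forget their initialization.  Post-warmup walker states are pooled
step-major and truncated to the requested draw count.  Identical seeds
reproduce identical draws bit-for-bit.

**Diagnostics.**  R-hat (rank-normalized split version) and effective sample
size are computed through ArviZ, with explicit pre-checks (≥ 2 chains, ≥ 10
draws, non-degenerate within-chain variance).  Summaries flag R-hat > 1.05
or ESS < 400; flags are carried in the summary metadata, never silently
dropped.

**HPDI.**  The 90% highest posterior density interval is the narrowest
contiguous window containing ⌈0.9·N⌉ sorted draws.  The raw
minimal-width-window estimator slides by sampling noise when the density is
flat near its optimum (errors of 0.02–0.05 at N = 100,000 standard-normal
draws), so the width sequence is smoothed by a moving average (bandwidth 20%
of candidate windows, reflect padding) before the argmin.  Calibration on
closed forms: max endpoint error 0.022 over 40 seeds for the standard
normal; exact boundary behaviour for the unit exponential (interval starts
at the mode); a known ~0.07 lower-bound slide (≈ 2% of interval width)
remains for strongly skewed shapes such as gamma(2).  The returned interval
always contains exactly ⌈mass·N⌉ draws.

## PLS correlation

The exploratory stage relates the full risk-trait block X (n×p, z-scored) to
the social-indicator block Y (n×q, z-scored) by partial least squares
correlation: the paired weight vectors (v_l, u_l) maximizing the covariance
of the variates X·v_l and Y·u_l are the left/right singular vectors of the
cross-covariance matrix X'Y/(n−1).  No deflation is applied — the
decomposition is symmetric in the two blocks.  Reported per mode: the
singular value, the Pearson correlation of the paired variates ("canonical
correlation"), the covariance-explained fraction s_l²/Σs² (the Σ running
over all min(p,q) singular values), weight loadings, and variate–variable
structure correlations.  Sign ambiguity is fixed by making the
largest-magnitude Y-weight entry of each mode positive.  The default mode
count is q, the social-indicator count.  PLS runs on unadjusted z-scored
blocks; residualizing age/sex first is left to the caller, as the analysis
is exploratory and uncertainty of the loadings is deliberately not
quantified.

## Missing data

Two single-imputation routes mirror what large- and medium-cohort analyses
do in practice:

* **Hot-deck** (nonparametric): each missing risk-trait cell is replaced by
  an observed value of the same variable from a donor drawn uniformly within
  the recipient's donor class — age decade × sex by default, falling back to
  the whole sample when a class has no donors.  It never invents values, is
  seeded, and under MCAR preserves each variable's distribution (KS distance
  < 0.05 at 10% missingness, n = 10,000).
* **Model-based Bayesian**: missing standardized covariate entries are
  declared latent quantities with standard-normal priors — consistent with
  the covariates being z-scored — and sampled jointly with the model
  parameters in a single step.  With 5% MCAR at n = 2,000 the posterior mean
  of the trait coefficient moves by < 0.03 relative to the complete-data
  run.

No multiple imputation with pooling is performed; both routes are single
procedures feeding one analysis.

## The synthetic cohort generator

The generator defines the study conditions for every test:

* Traits share one latent Gaussian factor with loading √trait_correlation
  (default 0.3), giving the collinearity typical of survey batteries.
  Continuous traits are the latent values; ordinal traits with k levels
  threshold the latent at equally spaced standard-normal quantiles (codes
  0..k−1); binary traits threshold at the median — matching the downstream
  treatment of all categoricals as ordinal numerics.
* Age is uniform on [40, 70] years (the recruitment window of the larger
  cohort; configurable); sex is Bernoulli(0.5).
* Each target is Bernoulli(logistic(intercept + Σ beta_j·z_j + agebeta·z_age
  + sexbeta·sex)) on the *standardized* traits, so the stated coefficients
  are exactly the marginal per-1-SD log-odds the models estimate.  The
  lack-of-support target uses its own coefficient vector (default 0.6× the
  loneliness vector), so the two targets associate through shared traits and
  correlated effects.  An optional participant-level latent component shared
  by both targets exists (`shared_target_sd`) but defaults to 0: any such
  component attenuates the marginal coefficients and would break the
  recovery contracts that define the test conditions.
* Missingness is MCAR or MAR-on-age; the latter scales masking probability
  by expit(z_age), renormalized so the expected overall fraction equals the
  requested rate.  Targets and confounds are never masked.  Neither
  mechanism claims fidelity to any real cohort, whose missingness process is
  unknown.

The two-block generator plants `n_latent` cross-correlated factor pairs
behind orthonormal weight matrices plus independent N(0, noise_sd²) column
noise.  Such noise attenuates the population mode correlation by
1/(1+noise_sd²); recovery checks use noise_sd = 0.1 (attenuation < 1%),
chosen as mild measurement noise on unit-variance factors.

What the generator does *not* emulate: variable-by-variable marginal
distributions of any real cohort, item-level response styles, informative
(MNAR) missingness, and household/geographic clustering.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated generating model, not epidemiological validity on real data.

## Effect reporting

A coefficient b (log-odds per 1 SD) is reported as odds ratio exp(b) and
percent change 100·(exp(b)−1).  The 90% interval is transformed
endpoint-wise — exact for a monotone map applied to a fixed interval, though
not identical to the HPDI of the transformed draws, which is also available
when draws are at hand.  Display precision is one decimal on percents,
three significant figures below 10%.  An optional rescaling divides b by the
trait's raw SD to express effects per raw unit.  Results tables group traits
by the four risk categories (lifestyle, physical, mental, societal) with
mean / 5% HPDI / 95% HPDI columns per target; bar-plot CSV exports carry
identical values.

## Problem sizes and defaults

Test and acceptance runs use the study conditions stated above: recovery and
calibration on 100 cohorts of n = 2,000 (true risktrait 0.5, agebeta 0.2,
sexbeta −0.3) with 2 chains × 1,000 draws per fit; PLS recovery at
n = 20,000; imputation checks at n = 10,000 (hot-deck) and n = 2,000
(latent-missing); closed-form HPDI checks at N = 100,000 draws.  Observed
under these conditions: |bias| < 0.01 and 87–89% HPDI coverage for the
recovery study; fitted mode correlations within 0.04 of the planted 0.7/0.3.

## Known limitations

* Ensemble "chains" are not literal single random-walk chains; pooled walker
  draws have mild intra-step correlation, so ESS estimates on them are
  approximate (diagnostic pre-checks and flags are unaffected).
* The HPDI smoothing trades a small slide bias on strongly skewed posteriors
  for a large variance reduction on flat ones (numbers above).
* The per-trait models condition on age and sex only; no joint model over
  all traits is fitted, so coefficients are marginal, not mutually adjusted.
* Cohort-scale findings (e.g., first-mode canonical correlations near 0.5,
  specific trait rankings) require the real microdata and are out of reach
  of the synthetic generator by design.
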