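"""Hierarchical Bayesian logistic regression of a binary social-isolation
target on one standardized risk trait, with age and sex confounds.

The model, fitted separately per (trait, target) pair:

    y ~ Bernoulli(p)
    logit(p) = alpha + x1 * risktrait + x2 * agebeta + x3 * sexbeta
    alpha    ~ Normal(0, 1)
    risktrait ~ Normal(mu_risk, sigma_risk)
    mu_risk  ~ Normal(0, 1)
    sigma_risk ~ HalfNormal(1)
    agebeta  ~ Normal(0, 1)
    sexbeta  ~ Normal(0, 1)

where x1 is the z-scored trait, x2 z-scored age, and x3 a 0/1 sex indicator.
The multilevel prior on the trait coefficient adapts its own scale to the
data.  Posterior integration uses MCMC (affine-invariant ensemble sampling
via emcee) on a non-centered, log-transformed parameterization —
``risktrait = mu_risk + sigma_risk * z`` with ``sigma_risk = exp(log_sigma)``
— which removes the funnel geometry of the hierarchical scale.

Missing covariate entries, when declared (see
:func:`isorisk.impute.declare_bayesian_missing`), become latent standard-
normal quantities sampled jointly with the model parameters.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.ndimage import uniform_filter1d
from scipy.special import expit
from scipy.stats import norm

import emcee

with _warnings.catch_warnings():
    _warnings.simplefilter("ignore")  # arviz emits a refactor FutureWarning on import
    import arviz as az

from .codebook import CohortTable

__all__ = [
    "RiskModelSpec",
    "PosteriorDraws",
    "ParamSummary",
    "PosteriorSummary",
    "build_risk_model",
    "sample_posterior",
    "hpdi",
    "r_hat",
    "effective_sample_size",
    "summarize",
]

PARAM_NAMES = ("alpha", "risktrait", "mu_risk", "sigma_risk", "agebeta", "sexbeta")
_STD_TOL = 1e-6
_LOG_HALFNORMAL_CONST = 0.5 * math.log(2.0 / math.pi)

# default convergence flags: potential-scale-reduction and effective-sample-size
RHAT_FLAG = 1.05
ESS_FLAG = 400.0


@dataclass(frozen=True)
class RiskModelSpec:
    """Data and priors of one per-trait model; evaluates its own log-posterior.

    ``missing_idx`` lists positions of the trait vector treated as latent
    standard-normal quantities (the corresponding ``risk`` entries are
    placeholders and ignored).
    """

    y: np.ndarray
    risk: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    trait: str = "risktrait"
    target: str = "target"
    missing_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_missing(self) -> int:
        return self.missing_idx.shape[0]

    @property
    def n_params(self) -> int:
        """Free parameters: the six model parameters plus one latent per missing cell."""
        return 6 + self.n_missing

    # -- natural-space log posterior (oracle-checkable) ---------------------
    def log_posterior(self, params: Sequence[float]) -> float:
        """Joint log density at ``(alpha, risktrait, mu_risk, sigma_risk,
        agebeta, sexbeta, *latent_missing)`` in natural parameter space."""
        params = np.asarray(params, dtype=float)
        if params.shape[0] != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {params.shape[0]}")
        alpha, beta, mu, sigma, agebeta, sexbeta = params[:6]
        if sigma <= 0:
            return -np.inf
        z_miss = params[6:]
        ll = self._log_likelihood(alpha, beta, agebeta, sexbeta, z_miss)
        lp = (
            norm.logpdf(alpha)
            + norm.logpdf(beta, loc=mu, scale=sigma)
            + norm.logpdf(mu)
            + (_LOG_HALFNORMAL_CONST - 0.5 * sigma**2)
            + norm.logpdf(agebeta)
            + norm.logpdf(sexbeta)
            + float(np.sum(norm.logpdf(z_miss)))
        )
        return float(ll + lp)

    def _risk_effective(self, z_miss: np.ndarray) -> np.ndarray:
        if self.n_missing == 0:
            return self.risk
        out = self.risk.copy()
        out[self.missing_idx] = z_miss
        return out

    def _log_likelihood(self, alpha, beta, agebeta, sexbeta, z_miss) -> float:
        if self.n == 0:
            return 0.0
        x1 = self._risk_effective(np.asarray(z_miss, dtype=float))
        eta = alpha + beta * x1 + agebeta * self.age + sexbeta * self.sex
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    # -- sampling-space (non-centered, log-sigma) density -------------------
    # theta columns: alpha, z_beta, mu_risk, log_sigma, agebeta, sexbeta, z_miss...
    def _logp_sampling(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        alpha = theta[:, 0]
        z_beta = theta[:, 1]
        mu = theta[:, 2]
        log_sigma = np.clip(theta[:, 3], -30.0, 30.0)
        agebeta = theta[:, 4]
        sexbeta = theta[:, 5]
        z_miss = theta[:, 6:]
        sigma = np.exp(log_sigma)
        beta = mu + sigma * z_beta

        if self.n:
            risk_eff = np.broadcast_to(self.risk, (theta.shape[0], self.n)).copy()
            if self.n_missing:
                risk_eff[:, self.missing_idx] = z_miss
            eta = (
                alpha[:, None]
                + beta[:, None] * risk_eff
                + agebeta[:, None] * self.age
                + sexbeta[:, None] * self.sex
            )
            ll = (self.y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        else:
            ll = np.zeros(theta.shape[0])

        std_normals = np.column_stack([alpha, z_beta, mu, agebeta, sexbeta])
        n_std = 5 + z_miss.shape[1]
        lp = (
            -0.5 * (std_normals**2).sum(axis=1)
            - 0.5 * (z_miss**2).sum(axis=1)
            - 0.5 * n_std * math.log(2.0 * math.pi)
        )
        # HalfNormal(1) prior on sigma plus the log-sigma Jacobian; the total
        # equals the natural-space log posterior plus 2*log_sigma
        lp = lp + _LOG_HALFNORMAL_CONST - 0.5 * sigma**2 + log_sigma
        return ll + lp

    def _neg_logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Value and gradient of -logp in sampling space (for MAP initialization)."""
        theta = np.asarray(theta, dtype=float)
        alpha, z_beta, mu, log_sigma, agebeta, sexbeta = theta[:6]
        z_miss = theta[6:]
        sigma = math.exp(min(log_sigma, 30.0))
        beta = mu + sigma * z_beta
        grad = np.zeros_like(theta)
        if self.n:
            x1 = self._risk_effective(z_miss)
            eta = alpha + beta * x1 + agebeta * self.age + sexbeta * self.sex
            resid = self.y - expit(eta)
            ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
            g_beta = float(resid @ x1)
            grad[0] = resid.sum()
            grad[1] = g_beta * sigma
            grad[2] = g_beta
            grad[3] = g_beta * sigma * z_beta
            grad[4] = float(resid @ self.age)
            grad[5] = float(resid @ self.sex)
            if self.n_missing:
                grad[6:] = beta * resid[self.missing_idx]
        else:
            ll = 0.0
        lp = (
            -0.5 * (alpha**2 + z_beta**2 + mu**2 + agebeta**2 + sexbeta**2)
            - 0.5 * float(z_miss @ z_miss)
            - 0.5 * (5 + z_miss.shape[0]) * math.log(2.0 * math.pi)
            + _LOG_HALFNORMAL_CONST
            - 0.5 * sigma**2
            + log_sigma
        )
        grad[:6] -= np.array([alpha, z_beta, mu, 0.0, agebeta, sexbeta])
        grad[3] += -(sigma**2) + 1.0
        if self.n_missing:
            grad[6:] -= z_miss
        return -(ll + lp), -grad


def _check_standardized_vec(x: np.ndarray, name: str, observed: np.ndarray | None = None):
    v = x if observed is None else x[observed]
    if v.size >= 2:
        if abs(v.mean()) > _STD_TOL or abs(v.std(ddof=1) - 1.0) > _STD_TOL:
            raise ValueError(
                f"{name} is not standardized (mean {v.mean():.3g}, sd {v.std(ddof=1):.3g}); "
                "z-score it first"
            )


def build_risk_model(table: CohortTable, trait: str, target: str) -> RiskModelSpec:
    """Assemble the per-trait model spec from a preprocessed cohort table.

    The trait column must already be z-scored and the target binary; age is
    z-scored here if it is not already (sex stays 0/1).
    """
    for col in (trait, target, "age", "sex"):
        if col not in table.data.columns:
            raise ValueError(f"column {col!r} not found in table")
    y = table.data[target].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"target {target!r} contains missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"target {target!r} must be binary 0/1")
    risk = table.data[trait].to_numpy(dtype=float)
    if np.isnan(risk).any():
        raise ValueError(
            f"trait {trait!r} contains missing values; impute first or declare them latent"
        )
    _check_standardized_vec(risk, f"trait {trait!r}")
    age = table.data["age"].to_numpy(dtype=float)
    if abs(age.mean()) > _STD_TOL or abs(age.std(ddof=1) - 1.0) > _STD_TOL:
        age = (age - age.mean()) / age.std(ddof=1)
    sex = table.data["sex"].to_numpy(dtype=float)
    if not set(np.unique(sex)) <= {0.0, 1.0}:
        raise ValueError("sex must be coded 0/1")
    return RiskModelSpec(y=y, risk=risk, age=age, sex=sex, trait=trait, target=target)


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws, one (chains x draws) matrix per parameter."""

    params: dict[str, np.ndarray]
    seed: int
    warmup: int
    sampler: str
    warnings: list[str] = field(default_factory=list)
    imputed: np.ndarray | None = None  # chains x draws x n_missing
    trait: str = "risktrait"
    target: str = "target"

    @property
    def chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)


def sample_posterior(
    model: RiskModelSpec,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
) -> PosteriorDraws:
    """MCMC sampling of the joint posterior.

    Each chain is an independent affine-invariant ensemble initialized with a
    seeded scatter around the posterior mode; post-warmup walker draws are
    pooled (step-major) and truncated to ``draws`` per chain.  Four chains are
    the default exploration mode; pass ``chains=1`` for a final single-chain
    solution.  Identical seeds reproduce identical draws.
    """
    if chains < 1:
        raise ValueError("chains must be >= 1")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if warmup < 0:
        raise ValueError("warmup must be >= 0")

    ndim = model.n_params
    nwalkers = max(2 * ndim + 2, 16)
    nwalkers += nwalkers % 2
    keep_steps = -(-draws // nwalkers)
    # ensemble samplers need a minimum number of moves to forget the
    # initialization regardless of the nominal warmup draw count
    warmup_steps = max(-(-warmup // nwalkers), 100)

    x0 = np.zeros(ndim)
    opt = optimize.minimize(model._neg_logp_grad, x0, jac=True, method="L-BFGS-B")
    mode = opt.x if np.isfinite(opt.fun) else x0

    master = np.random.default_rng(seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=(chains, 2))

    warn: list[str] = []
    per_chain = []
    imputed_chains = []
    for c in range(chains):
        rng = np.random.default_rng(int(chain_seeds[c, 0]))
        p0 = mode + 0.3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, model._logp_sampling, vectorize=True)
        state = emcee.State(
            p0, random_state=np.random.RandomState(int(chain_seeds[c, 1])).get_state()
        )
        sampler.run_mcmc(state, warmup_steps + keep_steps, progress=False)
        accept = float(np.mean(sampler.acceptance_fraction))
        if accept < 0.1:
            warn.append(f"chain {c}: low ensemble acceptance fraction ({accept:.2f})")
        chain = sampler.get_chain(discard=warmup_steps)  # (keep_steps, nwalkers, ndim)
        flat = chain.reshape(keep_steps * nwalkers, ndim)[:draws]
        per_chain.append(flat)

    theta = np.stack(per_chain)  # chains x draws x ndim
    sigma = np.exp(theta[..., 3])
    params = {
        "alpha": theta[..., 0],
        "risktrait": theta[..., 2] + sigma * theta[..., 1],
        "mu_risk": theta[..., 2],
        "sigma_risk": sigma,
        "agebeta": theta[..., 4],
        "sexbeta": theta[..., 5],
    }
    imputed = theta[..., 6:] if model.n_missing else None
    return PosteriorDraws(
        params=params,
        seed=seed,
        warmup=warmup,
        sampler="emcee affine-invariant ensemble (non-centered parameterization)",
        warnings=warn,
        imputed=imputed,
        trait=model.trait,
        target=model.target,
    )


def hpdi(draws: Sequence[float], mass: float = 0.9) -> tuple[float, float]:
    """Highest posterior density interval: the narrowest contiguous window of
    ``ceil(mass * N)`` sorted draws.

    The window-width sequence is jagged for flat densities (the minimal-width
    window "slides" by sampling noise), so the argmin is taken over a
    moving-average-smoothed width sequence (bandwidth 20% of the candidate
    windows, skipped when there are fewer than 100).  The returned interval
    always contains exactly ``ceil(mass * N)`` draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.shape[0]
    if n < 10:
        raise ValueError("hpdi requires at least 10 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    if widths.shape[0] > 100:
        h = max(3, int(round(0.2 * widths.shape[0])) | 1)
        widths = uniform_filter1d(widths, size=h, mode="reflect")
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _check_chains(draws: np.ndarray) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a chains x draws matrix")
    if arr.shape[0] < 2:
        raise ValueError("at least 2 chains required")
    if arr.shape[1] < 10:
        raise ValueError("at least 10 draws per chain required")
    if np.any(arr.var(axis=1) == 0.0):
        raise ValueError("degenerate chain with zero within-chain variance")
    return arr


def r_hat(draws: np.ndarray) -> float:
    """Potential scale reduction (rank-normalized split R-hat) across chains."""
    return float(az.rhat(_check_chains(draws)))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size across chains."""
    return float(az.ess(_check_chains(draws)))


@dataclass
class ParamSummary:
    mean: float
    hpdi_low: float
    hpdi_high: float
    r_hat: float
    ess: float


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, HPDI bounds and convergence diagnostics."""

    params: dict[str, ParamSummary]
    mass: float
    warnings: list[str] = field(default_factory=list)
    trait: str = "risktrait"
    target: str = "target"

    def __getitem__(self, name: str) -> ParamSummary:
        return self.params[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mean": {k: v.mean for k, v in self.params.items()},
                "hpdi_low": {k: v.hpdi_low for k, v in self.params.items()},
                "hpdi_high": {k: v.hpdi_high for k, v in self.params.items()},
                "r_hat": {k: v.r_hat for k, v in self.params.items()},
                "ess": {k: v.ess for k, v in self.params.items()},
            }
        )


def summarize(draws: PosteriorDraws, mass: float = 0.9) -> PosteriorSummary:
    """Mean, HPDI, R-hat and ESS per parameter; flags poor convergence
    (R-hat > 1.05 or ESS < 400) in the summary's warnings."""
    params: dict[str, ParamSummary] = {}
    warn = list(draws.warnings)
    for name, arr in draws.params.items():
        flat = arr.reshape(-1)
        lo, hi = hpdi(flat, mass) if flat.size >= 10 else (float(flat.min()), float(flat.max()))
        try:
            rh = r_hat(arr)
        except ValueError:
            rh = float("nan")
        try:
            ess = effective_sample_size(arr) if arr.shape[0] >= 2 else float(az.ess(arr))
        except ValueError:
            ess = float("nan")
        params[name] = ParamSummary(float(flat.mean()), lo, hi, rh, ess)
        if np.isfinite(rh) and rh > RHAT_FLAG:
            warn.append(f"{name}: r_hat = {rh:.3f} exceeds {RHAT_FLAG}")
        if np.isfinite(ess) and ess < ESS_FLAG:
            warn.append(f"{name}: effective sample size {ess:.0f} below {ESS_FLAG:.0f}")
    return PosteriorSummary(
        params=params, mass=mass, warnings=warn, trait=draws.trait, target=draws.target
    )


def with_missing(model: RiskModelSpec, missing_idx: np.ndarray) -> RiskModelSpec:
    """Return a copy of ``model`` whose listed trait entries are latent."""
    return replace(model, missing_idx=np.asarray(missing_idx, dtype=int))
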