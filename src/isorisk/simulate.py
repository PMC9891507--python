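"""Synthetic cohort generation with known ground truth.

Real population cohorts of this kind (hundreds of thousands of participants,
dozens of mixed binary/ordinal/continuous risk traits, age and sex confounds,
two binary social-isolation targets) cannot be redistributed, so every
downstream stage is exercised on simulated tables whose generating
coefficients are known exactly.

The generator draws correlated latent Gaussian traits (one shared factor, so
traits are collinear the way survey batteries are), discretizes them into the
declared types, and generates each binary target from a logistic model on the
*standardized* traits plus standardized age and a 0/1 sex indicator:

    y_i ~ Bernoulli( logistic( alpha + sum_j beta_j z_ij
                               + beta_age z_age,i + beta_sex sex_i ) )

so every beta is a log-odds change per 1 SD of its trait, matching how the
fitted models are parameterized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .codebook import CohortTable

__all__ = [
    "TraitSpec",
    "SimulationSpec",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_two_block",
    "inject_missingness",
    "default_trait_specs",
]

TARGETS = ("loneliness", "lack_social_support")


@dataclass(frozen=True)
class TraitSpec:
    """One risk trait: name, type and risk category."""

    name: str
    kind: str  # "binary" | "ordinal" | "continuous"
    category: str  # "lifestyle" | "physical" | "mental" | "societal"
    n_levels: int = 2  # ordinal only

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"trait {self.name}: unknown kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_levels < 2:
            raise ValueError(f"trait {self.name}: ordinal n_levels must be >= 2")


def default_trait_specs() -> list[TraitSpec]:
    """A representative battery of 16 mixed-type traits across four categories."""
    return [
        TraitSpec("current_tobacco_smoking", "ordinal", "lifestyle", 3),
        TraitSpec("alcohol_intake_frequency", "ordinal", "lifestyle", 5),
        TraitSpec("sleep_duration", "continuous", "lifestyle"),
        TraitSpec("tv_time", "continuous", "lifestyle"),
        TraitSpec("gym_attendance", "binary", "lifestyle"),
        TraitSpec("high_blood_pressure", "binary", "physical"),
        TraitSpec("diabetes", "binary", "physical"),
        TraitSpec("hearing_difficulty", "binary", "physical"),
        TraitSpec("vision_aid_user", "binary", "physical"),
        TraitSpec("neuroticism_score", "ordinal", "mental", 13),
        TraitSpec("felt_happy", "ordinal", "mental", 5),
        TraitSpec("depression_diagnosis", "binary", "mental"),
        TraitSpec("household_size", "ordinal", "societal", 6),
        TraitSpec("income_band", "ordinal", "societal", 5),
        TraitSpec("urban_residence", "binary", "societal"),
        TraitSpec("close_friends", "continuous", "societal"),
    ]


@dataclass
class SimulationSpec:
    """Generating model for a synthetic cohort.

    ``true_beta`` maps trait name to log-odds per 1 SD for the loneliness
    target; ``true_beta_support`` (default: 0.6x loneliness betas) drives the
    lack-of-support target, so the two targets share structure without being
    identical.  ``trait_correlation`` is the shared-factor variance fraction
    inducing collinearity among traits.  ``shared_target_sd`` optionally adds
    a participant-level latent component common to both targets' linear
    predictors (default off, keeping the stated betas exactly marginal).
    """

    n_participants: int
    trait_specs: list[TraitSpec] = field(default_factory=default_trait_specs)
    true_beta: dict[str, float] = field(default_factory=dict)
    true_beta_support: dict[str, float] | None = None
    true_age_beta: float = 0.0
    true_sex_beta: float = 0.0
    intercept: float = 0.0
    trait_correlation: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 70.0)
    shared_target_sd: float = 0.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.trait_correlation < 1.0:
            raise ValueError("trait_correlation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        names = [t.name for t in self.trait_specs]
        if len(set(names)) != len(names):
            raise ValueError("trait_specs contains duplicate names")
        for beta_map, label in ((self.true_beta, "true_beta"),
                                (self.true_beta_support or {}, "true_beta_support")):
            unknown = set(beta_map) - set(names)
            if unknown:
                raise ValueError(f"{label} refers to unknown traits: {sorted(unknown)}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing interval")
        if self.shared_target_sd < 0:
            raise ValueError("shared_target_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort (coefficients, prevalence, seed)."""

    true_beta: dict[str, float]
    true_beta_support: dict[str, float]
    true_age_beta: float
    true_sex_beta: float
    intercept: float
    trait_correlation: float
    prevalence: dict[str, float]
    missing_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _discretize(latent: np.ndarray, spec: TraitSpec) -> np.ndarray:
    if spec.kind == "continuous":
        return latent
    k = 2 if spec.kind == "binary" else spec.n_levels
    # threshold the standard-normal latent at equally spaced quantiles
    cuts = norm.ppf(np.arange(1, k) / k)
    return np.searchsorted(cuts, latent).astype(float)


def simulate_cohort(spec: SimulationSpec) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a cohort table plus its ground truth, reproducibly from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    traits = spec.trait_specs

    shared = rng.standard_normal(n)
    lam = np.sqrt(spec.trait_correlation)
    latent = lam * shared[:, None] + np.sqrt(1 - spec.trait_correlation) * rng.standard_normal(
        (n, len(traits))
    )
    values = {t.name: _discretize(latent[:, j], t) for j, t in enumerate(traits)}

    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    z_age = _standardize(age)
    z_traits = {name: _standardize(v) for name, v in values.items()}

    beta_support = (
        dict(spec.true_beta_support)
        if spec.true_beta_support is not None
        else {k: 0.6 * v for k, v in spec.true_beta.items()}
    )
    shared_u = spec.shared_target_sd * rng.standard_normal(n) if spec.shared_target_sd else 0.0

    prevalence = {}
    targets = {}
    for tname, betas in zip(TARGETS, (spec.true_beta, beta_support)):
        eta = spec.intercept + spec.true_age_beta * z_age + spec.true_sex_beta * sex + shared_u
        for trait, b in betas.items():
            eta = eta + b * z_traits[trait]
        y = rng.binomial(1, expit(eta)).astype(float)
        targets[tname] = y
        prevalence[tname] = float(y.mean())

    data = pd.DataFrame({CohortTable.ID: np.arange(1, n + 1)})
    for tname in TARGETS:
        data[tname] = targets[tname]
    data["age"] = age
    data["sex"] = sex
    for t in traits:
        data[t.name] = values[t.name]

    roles = {t: "target" for t in TARGETS}
    roles.update({"age": "confound", "sex": "confound"})
    roles.update({t.name: "risk_trait" for t in traits})
    categories = {t.name: t.category for t in traits}
    table = CohortTable(data, roles, categories)

    if spec.missing_rate > 0:
        mask_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missingness(table, spec.missing_rate, "MCAR", mask_seed)

    truth = SyntheticTruth(
        true_beta=dict(spec.true_beta),
        true_beta_support=beta_support,
        true_age_beta=spec.true_age_beta,
        true_sex_beta=spec.true_sex_beta,
        intercept=spec.intercept,
        trait_correlation=spec.trait_correlation,
        prevalence=prevalence,
        missing_fraction=table.missing_fraction(),
        seed=spec.seed,
    )
    return table, truth


def inject_missingness(
    table: CohortTable, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> CohortTable:
    """Mask risk-trait cells at the given expected rate; targets and confounds
    are never masked.

    ``MCAR`` masks uniformly at random.  ``MAR-on-age`` scales each
    participant's masking probability by ``expit(z_age)`` (renormalized to
    keep the expected overall fraction at ``rate``), so masking probability
    increases monotonically with age.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if mechanism not in ("MCAR", "MAR-on-age"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out = table.copy()
    if rate == 0.0 or not table.risk_traits:
        return out
    rng = np.random.default_rng(seed)
    n = table.n
    if mechanism == "MCAR":
        p_row = np.full(n, rate)
    else:
        if "age" not in table.data.columns:
            raise ValueError("MAR-on-age requires an 'age' column")
        w = expit(_standardize(table.data["age"].to_numpy(dtype=float)))
        p_row = np.clip(rate * w / w.mean(), 0.0, 1.0)
    for col in table.risk_traits:
        mask = rng.random(n) < p_row
        out.data.loc[mask, col] = np.nan
    return out


def simulate_two_block(
    n: int,
    p: int,
    q: int,
    n_latent: int,
    latent_corrs: Sequence[float],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Two z-scored data blocks sharing ``n_latent`` cross-correlated factors.

    Block X mixes factors ``f_l`` through orthonormal weights, block Y mixes
    partner factors ``h_l`` with corr(f_l, h_l) = latent_corrs[l]; independent
    N(0, noise_sd^2) noise is added per column.  Returns (X, Y, truth) where
    truth carries the orthonormal weight matrices and the latent correlations.
    Column noise attenuates the population mode correlation by a factor
    1/(1 + noise_sd^2).
    """
    if n_latent > min(p, q):
        raise ValueError("n_latent must not exceed min(p, q)")
    if len(latent_corrs) != n_latent:
        raise ValueError("latent_corrs must have length n_latent")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    f = rng.standard_normal((n, n_latent))
    corrs = np.asarray(latent_corrs, dtype=float)
    h = corrs * f + np.sqrt(1 - corrs**2) * rng.standard_normal((n, n_latent))

    def _orthonormal(dim: int) -> np.ndarray:
        m = rng.standard_normal((dim, max(n_latent, 1)))
        qmat, _ = np.linalg.qr(m)
        return qmat[:, :n_latent]

    w_x = _orthonormal(p)
    w_y = _orthonormal(q)
    X = (f @ w_x.T if n_latent else np.zeros((n, p))) + noise_sd * rng.standard_normal((n, p))
    Y = (h @ w_y.T if n_latent else np.zeros((n, q))) + noise_sd * rng.standard_normal((n, q))
    if n_latent == 0:  # pure-noise blocks need unit-scale columns to z-score
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    truth = {"x_weights": w_x, "y_weights": w_y, "latent_corrs": corrs}
    return X, Y, truth
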