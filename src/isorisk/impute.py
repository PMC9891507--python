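"""Missing-data handling: hot-deck donor substitution, or model-based
declaration of missing covariate entries as latent quantities.

Hot-deck imputation replaces each missing risk-trait value with an observed
value of the same variable drawn uniformly from a donor within the
recipient's donor class (default: age decade x sex), falling back to the
whole sample when a class has no observed donors.  It never invents values
and, under MCAR, preserves each variable's distribution.

The model-based alternative augments a fitted Bayesian risk model so that
every missing standardized covariate entry becomes a latent quantity with a
standard-normal prior, sampled jointly with the model parameters — a single
modeling step for target, covariates and missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import RiskModelSpec, with_missing
from .codebook import CohortTable

__all__ = [
    "ImputationSpec",
    "hot_deck_impute",
    "declare_bayesian_missing",
    "build_risk_model_with_missing",
]


@dataclass
class ImputationSpec:
    method: str = "hot_deck"  # "hot_deck" | "bayesian"
    donor_class_vars: tuple[str, ...] = ("age_decade", "sex")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("hot_deck", "bayesian"):
            raise ValueError(f"unknown imputation method {self.method!r}")


def _donor_classes(table: CohortTable, class_vars: tuple[str, ...]) -> np.ndarray:
    """Integer donor-class label per participant; 'age_decade' is derived."""
    if not class_vars:
        return np.zeros(table.n, dtype=int)
    cols = []
    for var in class_vars:
        if var == "age_decade" and "age_decade" not in table.data.columns:
            if "age" not in table.data.columns:
                raise ValueError("donor class 'age_decade' requires an 'age' column")
            cols.append((table.data["age"].to_numpy(dtype=float) // 10).astype(int))
        elif var in table.data.columns:
            cols.append(table.data[var].to_numpy())
        else:
            raise ValueError(f"donor class variable {var!r} not in table")
    import pandas as pd

    return pd.MultiIndex.from_arrays(cols).factorize()[0]


def hot_deck_impute(table: CohortTable, spec: ImputationSpec) -> CohortTable:
    """Fill all missing risk-trait cells with observed values of the same
    variable, drawn uniformly within the recipient's donor class.

    Returns a new table; also attaches an imputation log (count imputed per
    variable) as ``out.imputation_log``.  A variable with no observed value
    anywhere raises, naming it.
    """
    rng = np.random.default_rng(spec.seed)
    classes = _donor_classes(table, spec.donor_class_vars)
    out = table.copy()
    log: dict[str, int] = {}
    for col in table.risk_traits:
        x = out.data[col].to_numpy(dtype=float).copy()
        miss = np.isnan(x)
        log[col] = int(miss.sum())
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"variable {col!r} has no observed values to donate")
        observed_all = x[~miss]
        for cls in np.unique(classes[miss]):
            recipients = np.flatnonzero(miss & (classes == cls))
            donors = x[(classes == cls) & ~miss]
            if donors.size == 0:
                donors = observed_all
            x[recipients] = rng.choice(donors, size=recipients.size, replace=True)
        out.data[col] = x
    out.imputation_log = log  # type: ignore[attr-defined]
    return out


def declare_bayesian_missing(model: RiskModelSpec, missing_mask: np.ndarray) -> RiskModelSpec:
    """Augment a risk model so masked trait entries are latent N(0, 1)
    quantities sampled jointly with the model parameters.

    ``missing_mask`` is boolean with one entry per participant (shape (n,) or
    (n, 1)); observed entries stay fixed.  With an empty mask the model is
    returned with exactly the same number of free parameters.
    """
    mask = np.asarray(missing_mask, dtype=bool)
    if mask.ndim == 2 and mask.shape[1] == 1:
        mask = mask[:, 0]
    if mask.shape != (model.n,):
        raise ValueError(
            f"missing_mask shape {np.asarray(missing_mask).shape} does not match "
            f"the covariate vector length {model.n}"
        )
    return with_missing(model, np.flatnonzero(mask))


def build_risk_model_with_missing(
    table: CohortTable, trait: str, target: str
) -> RiskModelSpec:
    """Convenience: build the per-trait model from a table whose trait column
    still has NaNs, z-scoring on the observed entries and declaring the
    missing ones latent."""
    x = table.data[trait].to_numpy(dtype=float)
    mask = np.isnan(x)
    obs = x[~mask]
    if obs.size < 2 or obs.std(ddof=1) == 0:
        raise ValueError(f"trait {trait!r} has too few observed values to standardize")
    z = (x - obs.mean()) / obs.std(ddof=1)
    z[mask] = 0.0  # placeholder; overridden by the latent quantities

    y = table.data[target].to_numpy(dtype=float)
    if np.isnan(y).any() or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"target {target!r} must be binary 0/1 with no missing entries")
    age = table.data["age"].to_numpy(dtype=float)
    age = (age - age.mean()) / age.std(ddof=1)
    sex = table.data["sex"].to_numpy(dtype=float)
    model = RiskModelSpec(y=y, risk=z, age=age, sex=sex, trait=trait, target=target)
    return declare_bayesian_missing(model, mask)
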