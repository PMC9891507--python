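"""isorisk: population-level association of social isolation with dementia
risk factors.

The package links subjective (loneliness) and objective (lack of social
support) social isolation to candidate risk traits of Alzheimer's disease and
related dementias, the way large epidemiological cohort analyses do it:
codebook-driven harmonization of survey variables, missing-data imputation,
an exploratory two-block PLS correlation between the risk-trait and
social-indicator blocks, and — per trait — a hierarchical Bayesian logistic
regression with MCMC inference, HPDI summaries, and odds-scale reporting.
A synthetic cohort generator with known ground truth stands in for the
non-redistributable cohort microdata.
"""

from .codebook import (
    Codebook,
    CodebookEntry,
    CohortTable,
    binarize_target,
    recode_variable,
    zscore,
)
from .simulate import (
    SimulationSpec,
    SyntheticTruth,
    TraitSpec,
    default_trait_specs,
    inject_missingness,
    simulate_cohort,
    simulate_two_block,
)
from .impute import (
    ImputationSpec,
    build_risk_model_with_missing,
    declare_bayesian_missing,
    hot_deck_impute,
)
from .pls import PLSResult, covariance_explained, fit_pls, mode_correlations
from .bayes import (
    ParamSummary,
    PosteriorDraws,
    PosteriorSummary,
    RiskModelSpec,
    build_risk_model,
    effective_sample_size,
    hpdi,
    r_hat,
    sample_posterior,
    summarize,
)
from .report import (
    OddsEffect,
    build_results_table,
    coef_to_odds_effect,
    export_barplot_data,
    run_pipeline,
    scan_traits,
)

__version__ = "0.1.0"


def demo_codebook() -> Codebook:
    """The shipped representative codebook (synthetic fixture, ~15 variables
    across the four risk categories plus two targets and two confounds)."""
    from importlib.resources import files

    return Codebook.from_csv(files("isorisk.data") / "codebook_demo.csv")
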