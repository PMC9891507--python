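import warnings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

import numpy as np
import pytest

from isorisk import SimulationSpec, build_risk_model, simulate_cohort
from isorisk.simulate import TraitSpec


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-participant single-trait cohort with known generating model."""
    spec = SimulationSpec(
        n_participants=2000,
        trait_specs=[TraitSpec("risk_trait", "continuous", "lifestyle")],
        true_beta={"risk_trait": 0.5},
        true_age_beta=0.2,
        true_sex_beta=-0.3,
        seed=11,
    )
    table, truth = simulate_cohort(spec)
    return table, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    table, _ = small_cohort
    return build_risk_model(table.zscored(), "risk_trait", "loneliness")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
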