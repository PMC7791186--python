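import numpy as np
import pytest

from growthsde import CohortDesign, SDEModelSpec, ou_model, simulate_cohort
from growthsde.simulate import random_linear_sde  # noqa: F401  (re-export for tests)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ou():
    """Mean-reverting OU model: alpha=1.2, beta=-0.8, sigma=0.6."""
    return ou_model(1.2, -0.8, 0.6)


@pytest.fixture
def cubic():
    """Cubic-drift model with mean reversion."""
    return SDEModelSpec(
        drift_order=3,
        mean_reversion=True,
        params={
            "a1": -0.5,
            "a2": 0.1,
            "a3": 0.02,
            "a4": -0.003,
            "a5": 0.0001,
            "s": 0.5,
        },
    )


@pytest.fixture(scope="session")
def small_cohort():
    """40 children, 2 sites, complete monthly visits; OU-generated."""
    model = ou_model(1.2, -0.8, 0.6)
    design = CohortDesign(
        n_children_per_site=20,
        sites=("haydom", "venda"),
        p_visit_missing=0.0,
        seed=11,
        initial_mean=-0.8,
        initial_sd=0.5,
    )
    return simulate_cohort(model, design)


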