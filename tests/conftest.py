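import numpy as np
import pytest

from triopgs.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """150-trio cohort with default study parameters (shared, read-only)."""
    cfg = SimulationConfig(n_trios=150, n_snps=60, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """2000-trio cohort under random mating with a nonzero direct effect."""
    cfg = SimulationConfig(
        n_trios=2000,
        n_snps=400,
        delta_by_age={11: 0.3},
        eta_by_age={11: 0.0},
        sex_effect=0.0,
        ses_effect=0.0,
        ages=(11,),
        seed=21,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
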