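import numpy as np
import pytest

from telosim import CohortParams, default_params, estimate_power, simulate_cohort


@pytest.fixture(scope="session")
def defaults() -> CohortParams:
    return default_params()


@pytest.fixture(scope="session")
def small_cohort(defaults):
    """One default n=20 cohort with both tracks."""
    return simulate_cohort(defaults, seed=7)


@pytest.fixture(scope="session")
def large_cohort(defaults):
    """A million-person default cohort for moment checks."""
    return simulate_cohort(defaults.replace(n_individuals=1_000_000), seed=11)


@pytest.fixture(scope="session")
def power_curve(defaults):
    """Power of all strategies/assays at d = 0.5 over the default n grid.

    1,000 replicates per sample size with common random numbers across
    strategies and assays; shared session-wide because it is the
    costliest Monte-Carlo object in the suite.
    """
    params = defaults.replace(exposure_effect_d=0.5, exposure_fraction=0.5)
    return estimate_power(params, n_replicates=1000, alpha=0.05, seed=1234)


def row_pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])
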