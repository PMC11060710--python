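import warnings

import numpy as np
import pandas as pd
import pytest

from phenorisk import GeneratorConfig, generate_cohort

# the low-events warning fires by design in small test cohorts
warnings.filterwarnings("ignore", message="only .* events for .* parameters")


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 4,000-participant synthetic cohort (fixed seed)."""
    return generate_cohort(GeneratorConfig(n_participants=4000, seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort.table


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def cox_fixture_50():
    """50 untied rows with two covariates and a known-seed hazard structure."""
    r = np.random.default_rng(77)
    n = 50
    x1 = r.standard_normal(n)
    x2 = r.standard_normal(n)
    t = r.exponential(scale=np.exp(-(0.5 * x1 - 0.3 * x2)))
    event = (r.uniform(size=n) < 0.8).astype(int)
    return pd.DataFrame({"time_years": t, "cancer": event, "x1": x1, "x2": x2})
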