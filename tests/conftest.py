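import numpy as np
import pandas as pd
import pytest

from prsimpact.synthetic import (GeneratorConfig, generate_cohort,
                                 generate_incidence_table,
                                 generate_population_structure)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest default-parameter cohort shared across tests (read-only)."""
    cfg = GeneratorConfig(n_individuals=6000, seed=7, n_centres=4)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def incidence_table() -> pd.DataFrame:
    return generate_incidence_table(seed=7)


@pytest.fixture(scope="session")
def population_structure() -> pd.DataFrame:
    return generate_population_structure(total=100_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
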