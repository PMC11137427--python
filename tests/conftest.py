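import pandas as pd
import pytest

from telecarbon.ingest import apply_filters
from telecarbon.synthetic import GeneratorConfig, generate_sessions


@pytest.fixture(scope="session")
def population_100k() -> pd.DataFrame:
    """A large synthetic population for distributional checks."""
    return generate_sessions(GeneratorConfig(n_sessions=100_000, seed=123))


@pytest.fixture(scope="session")
def retained_100k(population_100k) -> pd.DataFrame:
    retained, _ = apply_filters(population_100k)
    return retained


@pytest.fixture(scope="session")
def population_10k() -> pd.DataFrame:
    return generate_sessions(GeneratorConfig(n_sessions=10_000, seed=7))
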