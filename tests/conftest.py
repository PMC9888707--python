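import numpy as np
import pandas as pd
import pytest

from hlburden.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (n = 20,000), shared across tests."""
    return generate(GeneratorConfig(n_individuals=20_000, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for structural / round-trip tests."""
    return generate(GeneratorConfig(n_individuals=400, seed=5, gene_betas={"HLGA001": 0.9}))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def audiogram_rows():
    """Handcrafted single-individual audiogram helper."""

    def build(ind="A", date="2020-01-01", ear="left", conduction="air", thresholds=(10, 20, 30)):
        return pd.DataFrame(
            {
                "individual_id": ind,
                "date": date,
                "ear": ear,
                "conduction": conduction,
                "frequency_hz": [500.0, 1000.0, 2000.0],
                "threshold_db": list(thresholds),
            }
        )

    return build
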