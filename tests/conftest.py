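import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metaboprs import (
    ProbitMatrix,
    SimulationConfig,
    default_panel,
    generate_cohort,
    impute,
    probit_matrix,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=4000, n_metabolites=12, n_blocks=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def imputed_cohort(small_cohort):
    return impute(small_cohort)


@pytest.fixture(scope="session")
def probit_scores(imputed_cohort):
    return probit_matrix(imputed_cohort)


def make_probit_frame(rng: np.random.Generator, n: int, p: int) -> ProbitMatrix:
    """Standalone probit-score container over independent normal columns."""
    panel = default_panel(p, min(3, p))
    values = pd.DataFrame(rng.standard_normal((n, p)), columns=list(panel.names))
    return ProbitMatrix(values=values, panel=panel, n_nonmissing=values.notna().sum())
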