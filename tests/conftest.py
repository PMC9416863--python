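import pandas as pd
import pytest
from hypothesis import settings

from dualfactor import CohortConfig, generate_cohort, score_pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-student / 40-school cohort shared across tests."""
    table, truth = generate_cohort(CohortConfig(n_students=2000, n_schools=40, seed=101))
    return table, truth


@pytest.fixture(scope="session")
def scored_panel(small_cohort) -> pd.DataFrame:
    table, _ = small_cohort
    return score_pipeline(table).panel
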