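import dataclasses

import pytest

from eelvkit.study_data import paired_series
from eelvkit.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 14-animal cohort, seed 0."""
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_series(default_cohort):
    return paired_series(default_cohort.table)


@pytest.fixture(scope="session")
def complete_cohort():
    """Default design with no missingness (266 fully paired rows)."""
    return simulate_cohort(
        dataclasses.replace(CohortConfig(seed=1), missing_fraction=0.0)
    )
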