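import numpy as np
import pandas as pd
import pytest

from templag.io_profiles import AbundanceTable
from templag.synthetic_cohort import SyntheticTruth, generate_paired_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    return SyntheticTruth(
        n_participants=200,
        n_species=30,
        rho2=0.3,
        alpha=0.5,
        b=0.5,
        cprime=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    cohort, record = generate_paired_cohort(small_truth)
    return cohort, record


@pytest.fixture
def toy_table():
    """3 species x 4 samples, percent scale, columns summing to 100."""
    data = pd.DataFrame(
        {
            "s1": [50.0, 30.0, 20.0, 0.0],
            "s2": [25.0, 25.0, 25.0, 25.0],
            "s3": [90.0, 10.0, 0.0, 0.0],
            "s4": [1.0, 2.0, 3.0, 94.0],
        },
        index=["s__a", "s__b", "s__c", "s__d"],
    )
    return AbundanceTable(data, mode="percent", level="s__")
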