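import numpy as np
import pytest

from bmissde import CohortParams, default_conversion_model, generate_cohort, load_reference_table


@pytest.fixture(scope="session")
def reference_table():
    """Packaged 36-row (bmi, d_e, factor) reference table for the 32-cm phantom."""
    return load_reference_table()


@pytest.fixture(scope="session")
def body_model():
    return default_conversion_model(32)


@pytest.fixture(scope="session")
def default_cohort():
    """One shared 5000-patient synthetic cohort (seed 1, shipped defaults)."""
    return generate_cohort(CohortParams(n=5000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
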