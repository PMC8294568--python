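import pytest

from mmpkit.simulate import CohortConfig, generate_cohort, generate_worked_examples


@pytest.fixture(scope="session")
def examples():
    return generate_worked_examples()


@pytest.fixture(scope="session")
def cohort():
    """Study-scale cohort: 40 donors, two visits, default conditions."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(CohortConfig(seed=3, replicate_noise_cv=0.0))
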