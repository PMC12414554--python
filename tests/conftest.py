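import pytest

import persrisk as pr


@pytest.fixture(scope="session")
def complete_spec() -> pr.CohortSpec:
    """Mid-size cohort with no missingness (truth fully observable)."""
    return pr.CohortSpec(
        n_subjects=2000, missingness={}, outcome_missingness={}, seed=11
    )


@pytest.fixture(scope="session")
def complete_cohort(complete_spec):
    return pr.generate_cohort(complete_spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Default study conditions: n=801, oversampling, full missingness."""
    return pr.generate_cohort(pr.CohortSpec(seed=42))


@pytest.fixture(scope="session")
def updated_scheme():
    return pr.build_scheme("updated_pers")
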