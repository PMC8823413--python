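import pytest

from mciscore import CohortSpec, generate_cohort, make_worked_fixtures, prepare_cohorts


@pytest.fixture(scope="session")
def fixtures():
    return make_worked_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean synthetic cohort used across modules (no contaminants)."""
    spec = CohortSpec(n_female=250, n_male=250, seed=11,
                      baseline_only_rate=0.0, direct_to_ad_rate=0.0, missing_rate=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohorts(small_cohort):
    """The same cohort pushed through outcome derivation and inclusion."""
    return prepare_cohorts(small_cohort)
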