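import pytest

from nutrivalid.cohort import CohortParams, generate_cohort_bundle


@pytest.fixture(scope="session")
def noise_free_params():
    """Small cohort with every noise source off: exact-recovery regime."""
    return CohortParams(
        n_participants=5,
        seed=11,
        isotope_noise_sd_ppm=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_bundle(noise_free_params):
    return generate_cohort_bundle(noise_free_params)


@pytest.fixture(scope="session")
def study_bundle():
    """Default study conditions: n=20, realistic noise, both tools."""
    return generate_cohort_bundle(CohortParams(n_participants=20, seed=42))
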