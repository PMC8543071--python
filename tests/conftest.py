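import dataclasses

import pytest

from wmtempo.cohort import DesignSpec, GenerativeParams, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return dataclasses.replace(DesignSpec(), n_participants=6, rng_seed=11)


@pytest.fixture(scope="session")
def default_params():
    return GenerativeParams()


@pytest.fixture(scope="session")
def small_cohort(small_spec, default_params):
    """Six-participant default-design cohort with default generative params."""
    return generate_cohort(small_spec, default_params)


@pytest.fixture(scope="session")
def clean_params():
    """No contamination, homogeneous kappa: every trial survives preprocessing."""
    return dataclasses.replace(
        GenerativeParams(),
        contamination_rates={},
        interruption_kappa_factor=1.0,
        variable_onset_kappa_factor=1.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(small_spec, clean_params):
    return generate_cohort(small_spec, clean_params)
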