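import pytest

from lutadose import CohortConfig, generate_cohort, run_reference_dosimetry

from _helpers import constant_kinetics_config


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (fixed seed)."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def default_rm(default_cohort):
    """Reference-method records + fits for the default cohort."""
    records, fits = run_reference_dosimetry(default_cohort, return_fits=True)
    return records, fits


@pytest.fixture()
def frozen_config():
    return constant_kinetics_config()
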