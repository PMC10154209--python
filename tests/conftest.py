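import braakstager as bs
import numpy as np
import pytest


@pytest.fixture(scope="session")
def small_config():
    """A reduced study design used across tests to keep runtimes low."""
    return bs.GeneratorConfig(
        seed=123,
        n_cu=60,
        n_mci=25,
        n_ad=20,
        n_calibration=40,
        n_followup_1y=40,
        n_followup_2y=25,
        n_followup_both=15,
        n_psen1=10,
    )


@pytest.fixture(scope="session")
def small_calibration(small_config):
    return bs.generate_calibration_sample(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return bs.generate_cross_section(small_config)


@pytest.fixture(scope="session")
def fitted_stager(small_calibration):
    return bs.BraakStager().fit(small_calibration)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
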