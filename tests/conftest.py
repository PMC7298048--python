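import warnings

import pytest

from pdxtrial.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    from pdxtrial.fidelity import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-model simulated trial shared across tests (read-only)."""
    return simulate_cohort(SimConfig(n_models=12, seed=7))


@pytest.fixture(scope="session")
def small_responses(small_cohort):
    from pdxtrial.response import responses_from_measurements

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return responses_from_measurements(small_cohort.measurements)
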