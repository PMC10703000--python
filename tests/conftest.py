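import numpy as np
import pytest

from evoimmune import (
    ModelParameters,
    TreatmentSchedule,
    default_protocol,
    posterior_mean_parameters,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Published posterior-mean kinetic rates."""
    return posterior_mean_parameters()


@pytest.fixture(scope="session")
def immuno_schedule() -> TreatmentSchedule:
    return TreatmentSchedule(immuno_days=(7.0, 10.0, 13.0))


@pytest.fixture(scope="session")
def combo_schedule() -> TreatmentSchedule:
    return TreatmentSchedule(immuno_days=(7.0, 10.0, 13.0),
                             evo_days=(13.0, 14.0, 15.0, 16.0, 17.0))


@pytest.fixture(scope="session")
def six_arms():
    return default_protocol()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
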