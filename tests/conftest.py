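import warnings

import pytest

from cscdyn import ModelParams, get_scenario


@pytest.fixture(autouse=True)
def _quiet_amplitude_warnings():
    """Tests probe amplitudes outside the realistic band on purpose."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="relative noise amplitude", category=UserWarning
        )
        yield


@pytest.fixture(scope="session")
def fig1a_params() -> ModelParams:
    return get_scenario("fig1a").model


@pytest.fixture(scope="session")
def fig1b_params() -> ModelParams:
    return get_scenario("fig1b").model


@pytest.fixture(scope="session")
def fig5d_params() -> ModelParams:
    return get_scenario("fig5d").model
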