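import pytest

from lipidsce import (
    CurvatureParams,
    PsceParams,
    RescueScenario,
    generate_timecourse,
)


@pytest.fixture(scope="session")
def curvature_params():
    return CurvatureParams.from_yaml()


@pytest.fixture(scope="session")
def psce_params():
    return PsceParams.from_yaml()


@pytest.fixture(scope="session")
def default_timecourse():
    """Default choline-rescue scenario, fixed seed, shared across tests."""
    samples, truth = generate_timecourse(RescueScenario(seed=11))
    return samples, truth
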