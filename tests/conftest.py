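import numpy as np
import pytest

from xlqg import (
    ReachingParams,
    build_reaching_model,
    generate_fixture_models,
    solve,
)

# fixed seeds: fixture-suite generation and Monte Carlo streams
FIXTURE_SEED = 7
MC_SEED = 2022


@pytest.fixture(scope="session")
def basic_params():
    return ReachingParams()


@pytest.fixture(scope="session")
def basic_model(basic_params):
    return build_reaching_model(basic_params)


@pytest.fixture(scope="session")
def basic_solution(basic_model):
    return solve(basic_model)


@pytest.fixture(scope="session")
def noise_free_params():
    return ReachingParams(sigma_c=0.0)


@pytest.fixture(scope="session")
def noise_free_model(noise_free_params):
    return build_reaching_model(noise_free_params)


@pytest.fixture(scope="session")
def noise_free_solution(noise_free_model):
    return solve(noise_free_model)


@pytest.fixture(scope="session")
def fixture_models():
    return generate_fixture_models(25, seed=FIXTURE_SEED)
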