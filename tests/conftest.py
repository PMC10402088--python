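import numpy as np
import pytest

from flickerfit import (
    FlickerGLM,
    GroundTruth,
    build_orthonormal_basis,
    build_study_schedule,
    make_vertex_geometry,
    simulate_bold,
)


@pytest.fixture(scope="session")
def basis():
    return build_orthonormal_basis(seed=0)


@pytest.fixture(scope="session")
def schedules():
    return build_study_schedule(seed=1)


@pytest.fixture(scope="session")
def geometry():
    return make_vertex_geometry(5, seed=2)


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruth.noiseless()


@pytest.fixture(scope="session")
def noiseless_dataset(schedules, noiseless_truth, basis, geometry):
    return simulate_bold(schedules, noiseless_truth, basis, geometry, seed=3)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset, basis):
    return FlickerGLM(noiseless_dataset, basis).fit()


@pytest.fixture(scope="session")
def noisy_truth():
    return GroundTruth.default()


@pytest.fixture(scope="session")
def noisy_dataset(schedules, noisy_truth, basis, geometry):
    return simulate_bold(schedules, noisy_truth, basis, geometry, seed=3)


@pytest.fixture(scope="session")
def noisy_fit(noisy_dataset, basis):
    return FlickerGLM(noisy_dataset, basis).fit()
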