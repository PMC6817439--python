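import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hyperph.cohort import AcquisitionParams, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def low_lesion(params):
    """One stratified low-grade lesion: ROI-mean pH exactly 7.53."""
    return generate_cohort(1, 0, params, seed=3, sampling="stratified")[0]


@pytest.fixture(scope="session")
def high_lesion(params):
    """One stratified high-grade lesion: ROI-mean pH exactly 7.22."""
    return generate_cohort(0, 1, params, seed=5, sampling="stratified")[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
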