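import numpy as np
import pytest

from sensillab.sensillum import SensillumParams


@pytest.fixture(scope="session")
def quiet_params() -> SensillumParams:
    """Default sensillum with all animal/trial variability switched off."""
    return SensillumParams(fly_jitter_cv=0.0, trial_jitter_cv=0.0)


@pytest.fixture(scope="session")
def uncoupled_params(quiet_params) -> SensillumParams:
    import dataclasses

    return dataclasses.replace(quiet_params, g_ab=0.0, g_ba=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
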