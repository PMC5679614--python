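import numpy as np
import pytest

from r2tstar.signal_model import AcquisitionParams


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    """The default 10-echo acquisition (TE1 = 4 ms, dTE = 4 ms)."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def te(acq) -> np.ndarray:
    return acq.echo_times


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def worked_dataset():
    """Small frozen dataset for the partial-correlation oracles:
    8 subjects, two variables and two covariates."""
    x = np.array([12.1, 14.3, 13.7, 15.2, 11.8, 16.0, 14.9, 13.1])
    y = np.array([55.0, 61.2, 58.4, 66.1, 52.3, 69.5, 60.0, 57.7])
    cov = np.array([
        [34.0, 0.0],
        [41.0, 1.0],
        [29.0, 0.0],
        [55.0, 1.0],
        [62.0, 0.0],
        [47.0, 1.0],
        [38.0, 0.0],
        [51.0, 1.0],
    ])
    return x, y, cov
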