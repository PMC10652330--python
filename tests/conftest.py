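import warnings

import pytest

from mtmrs.synthetic_data import GroundTruth, simulate_session


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def noiseless_session():
    """One clean session (all conditions + control), kf_pi=0.2, T1=3.1."""
    return simulate_session(GroundTruth(noise_sd=0.0), seed=3)


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruth(noise_sd=0.0)
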