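import numpy as np
import pytest

from jajcat import DEFAULT_COEFFS, generate_bank, to_irt_params


@pytest.fixture(scope="session")
def coeffs():
    return DEFAULT_COEFFS


@pytest.fixture(scope="session")
def default_bank():
    """The default adaptive bank: 20 items per length 1..7."""
    return generate_bank(range(1, 8), 20, rng=12345)


@pytest.fixture(scope="session")
def length_params(coeffs):
    """IRT parameters per length 1..7 under the published calibration."""
    return {L: to_irt_params(coeffs, L) for L in range(1, 8)}


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
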