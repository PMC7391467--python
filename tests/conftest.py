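import numpy as np
import pytest

from gaborlift.bank import BankSpec, build_bank


@pytest.fixture(scope="session")
def small_bank():
    """Small, fast bank used by most transform tests."""
    return build_bank(BankSpec(K=8, omegas=(0.5, 1.0, 1.5), sigma=2.0))


@pytest.fixture(scope="session")
def denoise_bank():
    """The 64x64 enhancement-protocol bank (16 orientations, 14 frequencies)."""
    from gaborlift.presets import DENOISE_OMEGAS

    return build_bank(BankSpec(K=16, omegas=DENOISE_OMEGAS, sigma=2.0, M=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
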