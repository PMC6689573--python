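import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def gaussian(wl, mu, sigma, amp):
    return amp * np.exp(-((wl - mu) ** 2) / (2.0 * sigma**2))
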