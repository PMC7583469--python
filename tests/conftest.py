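import numpy as np
import pytest

from dtdmri import build_protocol


@pytest.fixture(scope="session")
def protocol():
    """The default 364-point acquisition scheme, shared across tests."""
    return build_protocol()


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal perturbed by complex Gaussian noise."""
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)
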