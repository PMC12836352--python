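import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from wgmsense.optics import OpticalConfig
from wgmsense.simulate import SynthConfig, generate_spectrum
from wgmsense.spectra import preprocess

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    """Default droplet-in-cytoplasm optics: n_LD 1.47, n_cell 1.36."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def noiseless_spectrum():
    """Noiseless TE+TM comb of a 60 μm droplet plus its truth record."""
    s, truth = generate_spectrum(SynthConfig(snr=np.inf))
    return preprocess(s), truth


@pytest.fixture(scope="session")
def snr40_spectrum():
    s, truth = generate_spectrum(SynthConfig(snr=40.0, seed=11))
    return preprocess(s), truth


def true_line_positions(truth) -> np.ndarray:
    return np.sort([line[2] for line in truth["lines"]])
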