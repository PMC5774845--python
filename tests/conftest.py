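import numpy as np
import pytest

from lingualsonar import geometry
from lingualsonar.acoustics import AcousticMedium, DirectionGrid
from lingualsonar.synthdata import SessionConfig, generate_session


@pytest.fixture(scope="session")
def head():
    """Simplified artificial head at 1 mm resolution (fast, BEM-capable)."""
    return geometry.build_simplified_head(40.0, 25.0, 25.0, edge_length=1.0)


@pytest.fixture(scope="session")
def medium():
    return AcousticMedium()


@pytest.fixture(scope="session")
def grid1():
    return DirectionGrid.default(step=1.0)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free, dropout-free session with the Gaussian truth beam."""
    cfg = SessionConfig(seed=11, noise_sigma_db=0.0, marker_dropout=0.0,
                        duration=6.0)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """1 dB noise, 5% marker dropout — the standard study condition."""
    cfg = SessionConfig(seed=12, noise_sigma_db=1.0, marker_dropout=0.05,
                        duration=6.0)
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
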