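import numpy as np
import pytest

from espectra import AcquisitionMetadata, SimulationConfig, generate_homogeneous

GEL = dict(E=5.2e3, R=8e-6, k=0.049)          # homogeneous soft-gel scenario
CELL = dict(E0=4.0e3, Eb=450.0, d0=300e-9)    # cortex-on-bulk cell scenario


@pytest.fixture
def metadata_gel():
    return AcquisitionMetadata(probe_radius=GEL["R"], spring_constant=GEL["k"])


@pytest.fixture
def noisy_gel_batch():
    """Small batch of noisy Hertzian curves with ground-truth manifest."""
    cfg = SimulationConfig(
        model="homogeneous", E=GEL["E"], R=GEL["R"], k=GEL["k"],
        noise_sigma_F=20e-12, n_curves=12, seed=20260920,
    )
    return generate_homogeneous(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(19)
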