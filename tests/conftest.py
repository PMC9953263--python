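import numpy as np
import pytest

import erythrokit as ek


@pytest.fixture
def rng():
    return np.random.default_rng(20230230 % (2**31))


@pytest.fixture(scope="session")
def control_recording():
    """Noisy control recording at desk scale (5k cells, 1% SLI noise)."""
    spec = ek.preset_population("Control", n_cells=5000, seed=7)
    cells = ek.sample_population(spec)
    return ek.simulate_oft_recording(cells, noise_rel=0.01, seed=8)


@pytest.fixture(scope="session")
def tax_recording():
    spec = ek.preset_population("TAX", n_cells=5000, seed=7)
    cells = ek.sample_population(spec)
    return ek.simulate_oft_recording(cells, noise_rel=0.01, seed=8)
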