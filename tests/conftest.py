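import numpy as np
import pytest

from dentseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Full 16-tooth phantom at 64^3, no abnormalities."""
    return generate_phantom(PhantomSpec(seed=7, missing_prob=0.0))


@pytest.fixture(scope="session")
def phantom64_missing():
    """Phantom with missing teeth and one metal insert."""
    return generate_phantom(PhantomSpec(seed=3, missing_prob=0.3, metal_count=1))


@pytest.fixture(scope="session")
def phantom_desk():
    """Desk-scale 48^3 phantom, 6 teeth per arch."""
    return generate_phantom(
        PhantomSpec(grid_shape=(48, 48, 48), teeth_per_arch=6, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
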