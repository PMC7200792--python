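import numpy as np
import pytest

from physennet import PhantomSpec, PropagationSpec, generate_phantom

# study conditions of the simulated bench: He-Ne laser, 8 um camera pitch
WAVELENGTH = 632.8e-9
PITCH = 8e-6


@pytest.fixture
def spec10mm() -> PropagationSpec:
    return PropagationSpec(WAVELENGTH, PITCH, 10e-3)


@pytest.fixture
def phantom32() -> np.ndarray:
    """Small smooth phantom (peak 1 rad) for fast forward-model tests."""
    return generate_phantom(PhantomSpec(size=32, n_features=3, seed=7))
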