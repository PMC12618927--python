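import numpy as np
import pytest

from wavecal.phantoms import PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def phantom32():
    """One deterministic 32x32 phantom."""
    return generate_phantom(PhantomSpec(height=32, width=32, seed=7)).pixels


@pytest.fixture(scope="session")
def phantom64_smooth():
    """Noise-free 64x64 phantom (smooth background + ellipses + lesions)."""
    return generate_phantom(
        PhantomSpec(height=64, width=64, noise_sigma=0.0, seed=11)
    ).pixels


@pytest.fixture(scope="session")
def phantom_suite():
    """Small fixture suite of varied 32x32 phantoms."""
    return [g.pixels for g in
            generate_dataset(8, PhantomSpec(height=32, width=32), seed=3)]
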