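import numpy as np
import pytest

import perfectavg as pa


@pytest.fixture(scope="session")
def phantom():
    """Structured 64x64 test image with multi-scale frequency content."""
    return pa.make_phantom(64, 64, seed=7)


@pytest.fixture(scope="session")
def const_noise_stack():
    """Constant base 100 + Gaussian sigma=10, 64 frames, unclipped."""
    base = np.full((64, 64), 100.0)
    spec = pa.NoisySeriesSpec(n_frames=64, sigma=10.0, seed=11)
    return pa.make_noisy_series(base, spec)


@pytest.fixture(scope="session")
def bleached_stack():
    """Constant base 80 under a (50, 0.05, 30) bleaching envelope, low noise."""
    base = np.full((32, 32), 80.0)
    spec = pa.NoisySeriesSpec(n_frames=64, sigma=0.5, seed=13, bleach=(50.0, 0.05, 30.0))
    return pa.make_noisy_series(base, spec)
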