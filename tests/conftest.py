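import numpy as np
import pytest

from hsipath.synthetic import PhantomSpec, calibrated_slide, generate_slide


@pytest.fixture(scope="session")
def quadrant_slide():
    """A small calibrated quadrant phantom shared across tests."""
    spec = PhantomSpec(rows=120, cols=120, n_bands=30, margin=8, seed=11)
    tran, truth = calibrated_slide(spec)
    return spec, tran, truth


@pytest.fixture(scope="session")
def stripes_slide_noiseless():
    """Column-homogeneous noise-free phantom (calibration is exactly invertible)."""
    spec = PhantomSpec(
        rows=80, cols=60, n_bands=20, margin=10, layout="stripes", noise_sd=0.0, seed=7
    )
    raw, truth = generate_slide(spec)
    return spec, raw, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
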