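import numpy as np
import pytest

import thermowire as tw


@pytest.fixture(scope="session")
def default_truth():
    """Gaussian hotspot following the log heating model, 120 dynamics at 1 Hz."""
    params = tw.EqOneParams(alpha=0.02, tau=10.0, p0=30.0)
    window = tw.HeatingWindow(10.0, 90.0)
    phantom = tw.PhantomSpec()
    return tw.simulate_temperature_field(
        phantom, params, window, np.arange(120.0)
    )


@pytest.fixture(scope="session")
def noiseless_series(default_truth):
    return tw.simulate_complex_series(
        default_truth, noise=tw.NoiseDriftSpec(complex_noise_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def background_mask(default_truth):
    """Mask of pixels far from the hotspot (true background)."""
    ph = default_truth.phantom
    mask = np.ones(ph.grid, dtype=bool)
    s, r, c = ph.hotspot_center
    mask[:, r - 12 : r + 13, c - 12 : c + 13] = False
    return mask
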