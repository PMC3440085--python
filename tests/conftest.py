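import numpy as np
import pytest

from qhtscall import HillParams, Profile, concentration_grid, hill_response


@pytest.fixture(scope="session")
def grid14():
    return concentration_grid(14)


@pytest.fixture
def make_profile(grid14):
    """Factory for noiseless or noisy Hill profiles on the 14-point grid."""

    def _make(r0=0.0, rmax=100.0, ac50=0.1, slope=1.0, sigma=0.0, seed=0, sid="sub"):
        mu = hill_response(HillParams(r0, rmax, ac50, slope), grid14)
        if sigma > 0:
            mu = mu + np.random.default_rng(seed).normal(0.0, sigma, grid14.size)
        return Profile(sid, grid14, mu)

    return _make
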