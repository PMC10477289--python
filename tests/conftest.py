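import numpy as np
import pytest

import vsbright as vb


@pytest.fixture(scope="session")
def lib():
    return vb.default_library()


@pytest.fixture(scope="session")
def random_spectrum(lib):
    """Factory for smooth, strictly positive absolute spectra."""

    def make(rng: np.random.Generator) -> vb.SpectralDistribution:
        grid = vb.CANONICAL_GRID
        vals = 0.05 * np.ones_like(grid)
        for _ in range(3):
            mu = rng.uniform(400, 720)
            sigma = rng.uniform(15, 80)
            amp = rng.uniform(0.2, 2.0)
            vals = vals + amp * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
        return vb.SpectralDistribution(grid, vals)

    return make


@pytest.fixture(scope="session")
def noisefree_sim():
    """Default 5x5 design simulated without observer noise."""
    return vb.simulate(vb.GeneratorConfig(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default design with the default observer noise (SD 5)."""
    return vb.simulate(vb.GeneratorConfig(noise_sd=5.0, seed=1))
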