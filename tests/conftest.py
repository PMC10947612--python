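import numpy as np
import pytest

import swdisp as sw


@pytest.fixture(scope="session")
def nondispersive_field():
    """Noiseless 2.5 m/s field on the phantom-like grid (seed 1)."""
    return sw.synthesize_field(sw.phantom_config(medium=2.5, seed=1))


@pytest.fixture(scope="session")
def zener_field():
    """Noiseless reference-Zener field on the phantom-like grid (seed 1)."""
    return sw.synthesize_field(sw.phantom_config(medium=sw.ZENER_REFERENCE, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def plane_wave_field():
    """Factory for bin-aligned plane-wave fields (clean f-k quadrants)."""

    def make(nx=64, nt=128, dx=0.5e-3, dt=2.4e-4, m_f=25, m_k=16,
             direction="rightward", amplitude=1.0):
        x = dx * np.arange(nx)[:, None]
        t = dt * np.arange(nt)[None, :]
        f0 = m_f / (nt * dt)
        xi = m_k / (nx * dx)
        sign = -1.0 if direction == "rightward" else 1.0
        v = amplitude * np.cos(2 * np.pi * (f0 * t + sign * xi * x))
        return sw.WaveField(v=v, dx=dx, dt=dt), f0, xi

    return make
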