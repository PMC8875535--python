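import numpy as np
import pytest

from haptenfit import ConjugateLadder, SimulationConfig
from haptenfit.simulate import simulate_spectrum


def make_sim(seed=0, n_max=14, **overrides):
    """Simulate one conjugate spectrum and the ladder used to fit it."""
    config = SimulationConfig(seed=seed, **overrides)
    spectrum, truth = simulate_spectrum(config)
    ladder = ConjugateLadder(
        M0=config.carrier_mass, delta=config.delta, z=2, n_min=0, n_max=n_max
    )
    return spectrum, truth, ladder


@pytest.fixture(scope="session")
def gaussian_curve():
    """Densely sampled unit Gaussian (sigma=1) on [-8, 8]."""
    x = np.linspace(-8.0, 8.0, 4001)
    return x, np.exp(-0.5 * x**2)
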