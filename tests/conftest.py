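import numpy as np
import pytest

from paramyloid.kinetics_model import InitialState, KineticParameters
from paramyloid.synth import GeneratorConfig, gen_tht_traces


@pytest.fixture(scope="session")
def ab42_params():
    """Secondary-nucleation-dominated parameter set (lambda/kappa ~ 0.06)."""
    return KineticParameters(k_n=3e-5, k_2=3e3, k_plus=1e6)


@pytest.fixture(scope="session")
def unseeded_init():
    return InitialState(m0=3e-6)


@pytest.fixture(scope="session")
def time_grid():
    return np.linspace(0.0, 30.0 * 3600.0, 400)


@pytest.fixture(scope="session")
def tht_dataset():
    """One noisy generated plate (5 Cu levels x 5 replicates) plus its truth."""
    cfg = GeneratorConfig(seed=11)
    traces, truth = gen_tht_traces(cfg)
    return cfg, traces, truth
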