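import numpy as np
import pytest

from neurogrowth import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_params():
    """A fast, feasible configuration for unit tests."""
    return ModelParams(
        n_neurons=30,
        domain_side=300.0,
        rho_migration=150.0,
        duration_days=0.05,
        seed=7,
    )
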