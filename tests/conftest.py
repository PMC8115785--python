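import numpy as np
import pytest

from predcoding.filters import NeuronSpec, bank_from_specs, build_filter_bank


@pytest.fixture(scope="session")
def type1_bank():
    """Single type-1 neuron, no spike costs."""
    return bank_from_specs([NeuronSpec("type1")], nu=0.0, mu=0.0)


@pytest.fixture(scope="session")
def pair_bank():
    """One on-cell and its off-cell, standard costs."""
    return build_filter_bank("homogeneous", 2, nu=1.5, mu=1.5)


@pytest.fixture(scope="session")
def mixed_bank_small():
    """Four neurons, one of each type-1/type-2 on/off kind."""
    return build_filter_bank("type1_type2", 4, nu=1.5, mu=1.5, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
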