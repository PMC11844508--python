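import numpy as np
import pytest

import tci


@pytest.fixture(scope="session")
def small_library():
    """2 sources, 3 tiers (0.4, 0.2, 0.1 s): 14 segments."""
    sources = [tci.SourceSound(f"s{k}") for k in range(2)]
    return tci.build_segment_library(sources, top_tier=0.4, n_tiers=3)


@pytest.fixture(scope="session")
def dyadic_library():
    """8 sources, 3 dyadic tiers (500, 250, 125 ms)."""
    sources = [tci.SourceSound(f"s{k:02d}") for k in range(8)]
    return tci.build_segment_library(sources, top_tier=0.5, n_tiers=3)


@pytest.fixture(scope="session")
def dyadic_sequences(dyadic_library):
    return tci.generate_sequences(dyadic_library, mode="per_duration", seed=11)


@pytest.fixture(scope="session")
def noiseless_neuron():
    window = tci.GammaWindow(0.03, tci.minimal_center(0.03, 2), 2)
    return tci.NeuronSpec("nl0", window, nonlinearity="identity", gain=1.0,
                          baseline_rate=0.0, feature_seed=3)
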