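import numpy as np
import pytest

import calentropy as ce


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spiky_trace():
    """A spike-dominated synthetic trace with default kinetics."""
    trace, _ = ce.gen_spike_trace(ce.SpikeTraceSpec(spike_rate=0.02, seed=4))
    return trace


@pytest.fixture
def chain_populations():
    """Two chain populations with a genuine predictability difference."""
    a = ce.gen_population(ce.symmetric_two_state(0.9), 100, seed=1, name="persistent")
    b = ce.gen_population(ce.symmetric_two_state(0.6), 100, seed=2, name="labile")
    return a, b
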