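import numpy as np
import pytest

from ctgnet.signal_core import CTGTrace
from ctgnet.synthetic import TraceGenParams, generate_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_trace():
    """30-min, 4 Hz trace with constant 140 bpm FHR and flat UC."""
    n = 7200
    return CTGTrace(fhr=np.full(n, 140.0), uc=np.full(n, 10.0), fs=4.0)


@pytest.fixture
def noiseless_params():
    """Generator settings with every stochastic nuisance switched off."""
    return TraceGenParams(variability_amp_bpm=0.0, dropout_fraction=0.0, fs=1.0)


def make_labeled_trace(label, seed, **overrides):
    params = TraceGenParams(**overrides)
    return generate_trace(params, label, np.random.default_rng(seed))
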