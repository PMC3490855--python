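import numpy as np
import pytest

import rdksim as r


@pytest.fixture
def default_spec() -> r.StimulusSpec:
    return r.make_stimulus_spec(direction_separation=30.0, coherence=1.0)


@pytest.fixture
def default_params() -> r.ParametricObserverParams:
    return r.ParametricObserverParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
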