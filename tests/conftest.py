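import numpy as np
import pytest

from coloqc import synthetic


@pytest.fixture(scope="session")
def scenario0():
    """One randomized withdrawal scenario, shared across test modules."""
    return synthetic.generate_scenario(synthetic.random_spec(0))


@pytest.fixture(scope="session")
def texture_frame(scenario0):
    """A sharp mucosa-texture frame from the shared scenario."""
    rec = next(r for r in scenario0.timeline.records if r.segment_kind == "effective")
    return scenario0.frames[rec.index]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
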