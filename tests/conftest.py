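import pytest

from varodds import SimulationConfig
from varodds.simulate import gen_toy_transcript


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def toy_plus(cfg):
    return gen_toy_transcript(cfg, strand="+")


@pytest.fixture(scope="session")
def toy_minus(cfg):
    return gen_toy_transcript(cfg, strand="-")
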