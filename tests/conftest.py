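import numpy as np
import pytest

from riderscout import ltr_detect, synth


@pytest.fixture(scope="session")
def default_params():
    return ltr_detect.DetectorParams()


@pytest.fixture(scope="session")
def trnas():
    return [synth.DEFAULT_TRNA]


@pytest.fixture(scope="session")
def planted_genome():
    """Standard synthetic genome: 12 intact elements, 3 solo LTRs,
    2 truncated copies."""
    genome, truth = synth.build_genome(synth.SynthSpec(seed=3))
    return genome, truth


@pytest.fixture(scope="session")
def annotated(planted_genome, trnas, default_params):
    genome, truth = planted_genome
    elements = ltr_detect.annotate_genome(genome, trnas, default_params)
    return genome, truth, elements


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
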