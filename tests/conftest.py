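import numpy as np
import pytest

from genomesim.coalescent import Demography, SampleConfig, simulate_genealogy
from genomesim.subst_models import CodonFrequencies, build_gtr, build_gy94


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def jc_model():
    return build_gtr(np.ones(6), np.full(4, 0.25))


@pytest.fixture
def neutral_codon_model():
    return build_gy94(1.0, 1.0, CodonFrequencies.equal())


@pytest.fixture
def small_tree(rng):
    """A 5-leaf coalescent genealogy, N=1000, contemporaneous sampling."""
    return simulate_genealogy(
        SampleConfig.contemporaneous(5), Demography.constant(1000), rng=rng
    )
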