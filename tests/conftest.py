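import numpy as np
import pytest

from tracemfa import synth
from tracemfa.model_io import parse_openflux


@pytest.fixture(scope="session")
def toy_nets():
    return synth.toy_networks()


@pytest.fixture(scope="session")
def liver():
    return synth.liver_toy()


@pytest.fixture(scope="session")
def noise_free_dataset(liver):
    exp = synth.SyntheticExperiment(liver, noise_sd=0.0, seed=11)
    return synth.generate_dataset(exp)


@pytest.fixture
def chain_net():
    return parse_openflux(
        "rxnID,rxnEQ,rxnCTrans,rxnType\n"
        "upt,A.ext = A,ab = ab,S\n"
        "r1,A = B,ab = ab,F\n"
        "rel,B = B.out,ab = ab,E\n"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
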