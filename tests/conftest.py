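import numpy as np
import pytest

from wormquant.genotypes import make_genotype


@pytest.fixture(scope="session")
def wt_spec():
    return make_genotype("WT")


@pytest.fixture(scope="session")
def daf2_spec():
    return make_genotype("daf-2", daf2=True)


@pytest.fixture(scope="session")
def lifespan_schedule():
    return np.arange(2.0, 82.0, 2.0)
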