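import numpy as np
import pytest

from rootedit.examples import demo_locus


@pytest.fixture(scope="session")
def ccr1_locus():
    """CCR1-like demonstration locus: two sense guides, cuts 64 bp apart."""
    return demo_locus("CCR1")


@pytest.fixture(scope="session")
def iaa9a_locus():
    """IAA9A-like demonstration locus: guide cuts 54 bp apart."""
    return demo_locus("IAA9A")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)
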