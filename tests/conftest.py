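import numpy as np
import pytest

from milkamp.digestion import load_rules

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rules():
    """Bundled rule table with the calibrated (low-specificity CT) default."""
    return load_rules()


@pytest.fixture(scope="session")
def rules_ct_high():
    return load_rules(chymotrypsin="high")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_sequence(rng, length, alphabet=RESIDUES):
    return "".join(rng.choice(list(alphabet), size=length))
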