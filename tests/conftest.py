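import numpy as np
import pytest

from smdcycle.synthetic import ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="session")
def toy():
    """Default 3-bead-per-monomer toy dimer with its eleven-restraint set."""
    return make_toy_dimer(ToyDimerSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
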