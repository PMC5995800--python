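import numpy as np
import pytest

import iopqsar as q


@pytest.fixture(scope="session")
def reference_activity():
    """The packaged 27-compound activity table."""
    return q.load_reference_activity()


@pytest.fixture(scope="session")
def small_library():
    """A small synthetic labelled library shared across tests."""
    mols, labels = q.gen_library(q.SimulationSpec(seed=42, n_active=15,
                                                  n_inactive=15))
    return mols, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
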