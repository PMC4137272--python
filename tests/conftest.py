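import logging

import numpy as np
import pytest

from pmgamm import synthetic as syn

logging.getLogger("pmgamm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """Desk-scale scenario shared across tests (150 sites, 3 regions, 24 m)."""
    return syn.scenario_default(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
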