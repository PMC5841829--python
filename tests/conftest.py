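import logging

import numpy as np
import pytest

from multicell.cell import Cell
from multicell.phenotype import default_phenotype

logging.getLogger("multicell").setLevel(logging.ERROR)
logging.getLogger().setLevel(logging.ERROR)


def make_mech_cell(cid, position):
    """A mechanics-only cell (no cycle/death) at the reference volume."""
    ph = default_phenotype()
    ph.death = None
    return Cell(cid, ph, position)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
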