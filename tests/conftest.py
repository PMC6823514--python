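import logging

import numpy as np
import pytest

from mmbscan.trees import RateCalibration, SpeciesTree

logging.getLogger("mmbscan").setLevel(logging.ERROR)
logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture
def calib():
    return RateCalibration()


@pytest.fixture
def ladder_tree():
    """Three-taxon ladder with Myr branch lengths 1, 2, 3."""
    return SpeciesTree.from_newick("((a:1,b:2):3,c:6);", unit="myr")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
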