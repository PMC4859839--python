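import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # test-local oracles

from pocket_eda import templates
from pocket_eda.eda import decompose
from pocket_eda.synthetic_data import (DimerScanSpec, HBondSpec,
                                       make_dimer_scan,
                                       make_hbond_trajectory)


@pytest.fixture(scope="session")
def water_dimer():
    """Hydrogen-bonded water dimer, O...O = 3.0 Å, minimal basis."""
    return make_dimer_scan(DimerScanSpec(
        templates.water("donor"), templates.water("acceptor"),
        separations=(3.0,)))[0]


@pytest.fixture(scope="session")
def water_dimer_eda(water_dimer):
    return decompose(water_dimer, label="water-dimer")


@pytest.fixture(scope="session")
def bimodal_trajectory():
    """20k-frame bimodal + unimodal synthetic trajectory, fixed seed."""
    specs = [
        HBondSpec("bimodal", ((0.6, 1.9, 0.08), (0.4, 2.9, 0.12)), 20000),
        HBondSpec("narrow", ((1.0, 2.0, 0.1),), 20000),
    ]
    return specs, make_hbond_trajectory(specs, seed=7)
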