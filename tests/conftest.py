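import numpy as np
import pytest

from thermalplex.panel import grid_scan
from thermalplex.spectrum import ThermalProbeSet
from thermalplex.thermo import BindingConditions


@pytest.fixture(scope="session")
def ref_conditions():
    """Reference binding conditions: 250 nM strand, 195 mM monovalent."""
    return BindingConditions(strand_conc_M=250e-9, salt_mM=195.0)


@pytest.fixture(scope="session")
def worked_probe(ref_conditions):
    """The worked-example probe: barcode Tm 61 deg C, quencher Tm 53 deg C."""
    return ThermalProbeSet.from_tms("apc", 61.0, 53.0, conditions=ref_conditions)


@pytest.fixture(scope="session")
def default_grid():
    """Full design-plane scan at the stock 1 deg C resolution."""
    return grid_scan()
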