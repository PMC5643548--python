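"""Shared fixtures: beam spectra and small track libraries.

Session-scoped Monte Carlo fixtures keep the unit suite fast; the
acceptance tests build their own full-scale libraries.
"""

import numpy as np
import pytest

from arpsim import GnpSpec, build_library, preset_spectrum
from arpsim.cell_model import CellGeometry
from arpsim.survival import RadiosensitivityParams


@pytest.fixture(scope="session")
def spectrum_100():
    return preset_spectrum("gulmay_100kvp")


@pytest.fixture(scope="session")
def spectrum_300():
    return preset_spectrum("gulmay_300kvp")


@pytest.fixture(scope="session")
def lib_100_19(spectrum_100):
    """Small 100 kVp / 1.9 nm library for unit tests."""
    return build_library(GnpSpec(1.9), spectrum_100, 1000, seed=101)


@pytest.fixture(scope="session")
def lib_100_30(spectrum_100):
    return build_library(GnpSpec(30.0), spectrum_100, 1000, seed=102)


@pytest.fixture(scope="session")
def lib_100_100(spectrum_100):
    return build_library(GnpSpec(100.0), spectrum_100, 1000, seed=103)


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()


@pytest.fixture(scope="session")
def params():
    return RadiosensitivityParams()
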