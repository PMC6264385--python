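import numpy as np
import pytest

from qdcm.oxygen import build_lookup
from qdcm.phantom import GasProtocol, make_protocol
from qdcm.physio import BloodConstants, derive_arterial
from qdcm.signals import AcquisitionParams

HB = 0.143  # g/ml, group-mean haemoglobin
P50 = 27.1  # mmHg


@pytest.fixture(scope="session")
def constants():
    return BloodConstants(hb=HB)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def lut():
    """Moderate-resolution lookup table shared across the suite."""
    base = build_lookup(np.geomspace(5.0, 150.0, 48),
                        np.geomspace(0.005, 0.35, 48), hb=HB, p50=P50)
    return base.resample(256, 256)


@pytest.fixture(scope="session")
def arterial(constants, acq):
    """Arterial state for the default 18-min gas protocol."""
    protocol = GasProtocol.default()
    trace = make_protocol(protocol)
    n = int(protocol.total_duration // acq.tr) // 2 * 2
    return derive_arterial(trace, np.arange(n) * acq.tr, constants)


@pytest.fixture(scope="session")
def flat_arterial(constants, acq):
    """Arterial state for an air-only (no modulation) protocol."""
    protocol = GasProtocol.flat(120, acq.tr)
    trace = make_protocol(protocol)
    return derive_arterial(trace, np.arange(120) * acq.tr, constants)
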