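import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mdmefit import SignalSet, TissueParams, load_presets, signal_set
from mdmefit.protocols import get_protocol
from mdmefit.signal import SignalSample

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def families():
    return load_presets()

@pytest.fixture(scope="session")
def etl1():
    return get_protocol("ETL1")


#: Canonical vial ground truths (T1 ms, T2 ms, A*PD) used throughout.
VIAL_TRUTHS = {
    "GM": (1100.0, 139.0, 400.0),
    "WM": (571.0, 135.0, 325.0),
    "CSF": (2543.0, 1790.0, 500.0),
}


def magnitude_signal_set(t1, t2, m0, protocol, b1=1.0, label="x") -> SignalSet:
    """Noise-free magnitude observations (|signed model|) for one voxel."""
    s = signal_set(TissueParams(label, t1, t2, 1.0), protocol, scale=m0, b1=b1)
    return SignalSet(
        tuple(SignalSample(v.te_ms, v.ti_ms, abs(v.intensity)) for v in s.samples),
        protocol_name=protocol.name)


@pytest.fixture(scope="session")
def vial_truths():
    return VIAL_TRUTHS
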