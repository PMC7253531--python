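import numpy as np
import pytest

from capheno import synthetic_data as sd
from capheno.trace_processing import NormalizedTrace, RawTrace


@pytest.fixture(scope="session")
def model():
    """Default transient model: 2% amplitude, τ = 1 s, 0.8% threshold."""
    return sd.TransientModel()


@pytest.fixture(scope="session")
def geometry():
    """Short 60-s recording at 20 FPS for fast unit tests."""
    return sd.AcquisitionGeometry(duration=60.0)


@pytest.fixture(scope="session")
def long_geometry():
    """Full-length 10-min recording at 20 FPS (the study condition)."""
    return sd.AcquisitionGeometry()


def make_normalized(values, fps=20.0, f0=100.0):
    return NormalizedTrace(values=np.asarray(values, float), f0=f0, fps=fps)


def make_raw(values, fps=20.0):
    return RawTrace(values=np.asarray(values, float), fps=fps)
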