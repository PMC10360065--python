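import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cbxscreen.config import AssayConfig


@pytest.fixture
def config() -> AssayConfig:
    return AssayConfig()


@pytest.fixture
def simple_series():
    """Tiny 3x4 series factory with controllable absorbance grid."""
    from cbxscreen.types import SpectralTimeSeries

    def make(absorbance, times=(180.0, 7200.0, 14400.0),
             wavelengths=(300.0, 320.0, 340.0, 360.0), well="A1",
             compound="cpdX"):
        return SpectralTimeSeries(
            well_id=well, compound_id=compound,
            timepoints=np.asarray(times, float),
            wavelengths=np.asarray(wavelengths, float),
            absorbance=np.asarray(absorbance, float))

    return make
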