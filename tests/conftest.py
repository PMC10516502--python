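import numpy as np
import pytest

from paleocoex.chronology.calibration import CalibrationCurve
from paleocoex.synthetic import WorldConfig, generate_toy_calibration_curve, generate_world


@pytest.fixture(scope="session")
def identity_curve() -> CalibrationCurve:
    """Toy curve where radiocarbon age equals calendar age, constant error."""
    return generate_toy_calibration_curve(window=(60.0, 0.0), wiggle_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def wiggly_curve() -> CalibrationCurve:
    return generate_toy_calibration_curve(window=(60.0, 0.0), wiggle_amplitude=300.0, seed=3)


@pytest.fixture(scope="session")
def doubling_curve() -> CalibrationCurve:
    """Curve with mu(theta) = 2 theta and negligible curve error."""
    cal = np.arange(0.0, 60001.0, 5.0)
    return CalibrationCurve(cal, 2.0 * cal, np.full_like(cal, 1e-6), name="mu=2theta")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world reused by several integration tests."""
    return generate_world(WorldConfig(n_regions=8, sites_per_region=8, seed=42))
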