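import numpy as np
import pytest

from hpaxis import IDENTITY, InterventionVector, calibrate_baseline


@pytest.fixture(scope="session")
def params():
    """Calibrated baseline parameters (Table-of-rates defaults, day units)."""
    return calibrate_baseline()


@pytest.fixture(scope="session")
def identity():
    return IDENTITY


def random_intervention(rng, lo=0.7, hi=1.5) -> InterventionVector:
    """A log-uniform intervention draw around identity (module-level helper)."""
    draw = lambda: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return InterventionVector(
        I1=draw(), I2=draw(), I3=draw(),
        A1=draw(), A2=draw(), A3=draw(),
        C1=draw(), C2=draw(), C3=draw(),
    )
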