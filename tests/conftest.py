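import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tractmat as tm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sheet() -> tm.MedialSurface:
    """Small flat fixture sheet: 20x10 vertices over 40x20 mm, radius 2 mm."""
    return tm.gen_surface("flat_sheet", 20, 10, (40.0, 20.0),
                          radius_spec={"kind": "constant", "r0": 2.0})


@pytest.fixture(scope="session")
def fine_sheet() -> tm.MedialSurface:
    """Fine 1 mm-spacing sheet for kernel-shape and null-field simulations."""
    return tm.gen_surface("flat_sheet", 61, 31, (60.0, 30.0))


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    return tm.gen_cohort(n=178, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
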