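import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import graftgauge as gg
from graftgauge import hemodynamics as hd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def unit_cylinder_20k():
    """Open unit cylinder (r=1, h=1) with >= 20k faces."""
    return gg.make_cylinder_mesh(1.0, 1.0, segments=(160, 64))


@pytest.fixture(scope="session")
def anatomy():
    return gg.AnatomyParams()


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient jittered cohort shared across tests."""
    return gg.make_cohort(gg.CohortSpec(n_patients=3, seed=1))


@pytest.fixture(scope="session")
def newtonian_rheology():
    """Quemada parameters degenerate to a Newtonian fluid (k0 == k_inf)."""
    return hd.RheologyParams(k0=2.0, k_inf=2.0)


@pytest.fixture(scope="session")
def waveforms():
    return [hd.make_waveform(k) for k in ("flat", "sharp", "real")]
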