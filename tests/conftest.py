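import numpy as np
import pytest

import mwablate as mw
from mwablate.study import StudyConfig, run_study


@pytest.fixture(scope="session")
def default_domain():
    return mw.build_default_geometry()


@pytest.fixture(scope="session")
def coarse_grid(default_domain):
    """Coarse conforming grid, adequate for structural/qualitative checks."""
    return mw.generate_grid(default_domain, 0.25e-3, 1.5e-3)


@pytest.fixture(scope="session")
def default_grid(default_domain):
    """The reference-resolution grid used by the full study."""
    return mw.generate_grid(default_domain)


@pytest.fixture(scope="session")
def port_245(default_domain):
    a = default_domain.antenna
    return mw.CoaxPortSpec(10.0, 2.45e9, a.r_inner_conductor, a.r_dielectric)


@pytest.fixture(scope="session")
def fast_study():
    """Coarse-grid four-frequency inflated/deflated sweep (qualitative)."""
    cfg = StudyConfig(states=("inflated", "deflated")).fast()
    return run_study(cfg)


@pytest.fixture(scope="session")
def full_study():
    """Reference-resolution four-frequency inflated/deflated sweep."""
    cfg = StudyConfig(states=("inflated", "deflated"))
    return run_study(cfg)
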