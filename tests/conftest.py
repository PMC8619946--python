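import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dpitrack import analytic_swirl_field, build_geometry
from dpitrack.fixtures import get_formulation
from dpitrack.tracker import run_simulation
from dpitrack.wallmodel import MaterialParams

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def materials():
    return MaterialParams()


@pytest.fixture(scope="session")
def swirl_field(geometry):
    # 60 L/min operating point
    return analytic_swirl_field(geometry, 1.0e-3)


@pytest.fixture(scope="session")
def default_run(geometry, swirl_field):
    """Reference 100-particle run of formulation F1 at 60 L/min, seed 42."""
    records, impacts = run_simulation(
        get_formulation("F1"), geometry, swirl_field, 100, seed=42, collect_impacts=True
    )
    return records, impacts


@pytest.fixture(scope="session")
def wide_span_run(geometry, swirl_field):
    """Larger run of the widest-span formulation (F4) for impact statistics."""
    records, impacts = run_simulation(
        get_formulation("F4"), geometry, swirl_field, 250, seed=7, collect_impacts=True
    )
    return records, impacts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
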