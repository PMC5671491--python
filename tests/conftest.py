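import math

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from gdgtproxy import GDGTProfile, load_table1_fixture, normalize_profile

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def flat_profile():
    """An already-normalized reference profile."""
    return GDGTProfile(g0=50, g1=10, g2=10, g3=10, g4=5, cren=10, cren_iso=5)


def normalized_profiles():
    """Strategy: valid GDGT profiles normalized to 100 percent."""
    component = st.floats(0.0, 1.0, allow_nan=False)
    return (
        st.tuples(*[component] * 7)
        .filter(lambda t: sum(t) > 1e-3)
        .map(lambda t: normalize_profile(GDGTProfile(*t)))
    )


def assert_close(a: float, b: float, tol: float = 1e-9) -> None:
    assert math.isfinite(a) and math.isfinite(b) and abs(a - b) <= tol, (a, b)
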