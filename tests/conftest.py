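"""Shared fixtures: model instances and settled resting states.

Classification horizons/steps used in tests trade a little runtime for
none of the physics: the dimensionless models are piecewise-linear or
cubic with eigenvalues well below 1, so dt = 0.02 keeps RK4 error far
below every tolerance asserted here, and 60 time units comfortably cover
every spike/no-spike decision.  HH runs at dt = 0.01 ms with a 50 ms
window.
"""

import pytest

from sepx import dynamics, get_model

# classification settings reused across the suite
FAST = dict(t_end=60.0, dt=0.02)  # dimensionless models
HHSET = dict(t_end=50.0, dt=0.01)  # HH (ms)


@pytest.fixture(scope="session")
def qif():
    return get_model("qif")


@pytest.fixture(scope="session")
def pwl2d():
    return get_model("pwl2d")


@pytest.fixture(scope="session")
def pwl3d():
    return get_model("pwl3d")


@pytest.fixture(scope="session")
def fhn():
    return get_model("fhn")


@pytest.fixture(scope="session")
def boltzmann():
    return get_model("boltzmann-fhn")


@pytest.fixture(scope="session")
def hh():
    return get_model("hh")


@pytest.fixture(scope="session")
def hh_rest(hh):
    return dynamics.rest_state(hh)


@pytest.fixture(scope="session")
def pwl2d_rest(pwl2d):
    return dynamics.rest_state(pwl2d)
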