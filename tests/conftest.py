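import numpy as np
import pytest

from fluxcorners import make_fixture


@pytest.fixture(scope="session")
def chain_fx():
    return make_fixture("chain", length=2)


@pytest.fixture(scope="session")
def diamond_fx():
    return make_fixture("diamond")


@pytest.fixture(scope="session")
def interval_fx():
    return make_fixture("interval")  # free branch flux spans [0, 10]


@pytest.fixture(scope="session")
def simplex_fx():
    return make_fixture("simplex", n_branches=3)


@pytest.fixture(scope="session")
def cycle_fx():
    return make_fixture("cycle")


@pytest.fixture(scope="session")
def planted_fx():
    return make_fixture("planted_regulation")


def steady_state_residual(model, v: np.ndarray) -> float:
    return float(np.max(np.abs(model.S @ v), initial=0.0))


def bound_violation(model, v: np.ndarray) -> float:
    return float(max(
        np.max(model.lower_bounds - v, initial=0.0),
        np.max(v - model.upper_bounds, initial=0.0),
    ))
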