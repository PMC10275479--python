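import pytest
from hypothesis import settings

import gba

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FIXTURE_NAMES = ["A", "B", "C", "redundant"]


@pytest.fixture(scope="session")
def model_a():
    return gba.builtin_model("A")


@pytest.fixture(scope="session")
def model_b():
    return gba.builtin_model("B")


@pytest.fixture(scope="session")
def model_c():
    return gba.builtin_model("C")


@pytest.fixture(scope="session")
def model_redundant():
    return gba.builtin_model("redundant")


@pytest.fixture(scope="session")
def models():
    return {name: gba.builtin_model(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def optima(models):
    """Converged optimum for every builtin fixture (shared across tests)."""
    return {
        name: gba.maximize_growth(m, n_starts=20, seed=1, tol=1e-6)
        for name, m in models.items()
    }


def interior_points(model, n, seed, margin=0.02):
    """Random feasible flux fractions kept well inside the positivity boundary.

    Finite-difference oracles need concentrations away from the kinetic
    singularity at c = 0, so these points carry a larger interior margin
    than the optimizer's default starts.
    """
    return gba.initial_points(model, n, seed, margin=margin)
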