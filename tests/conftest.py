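import numpy as np
import pytest

from covfes.surfaces import make_reaction_surface, surface_ground_truth


@pytest.fixture(scope="session")
def surface_78():
    """Reaction surface calibrated to barrier 7.8, ΔA −10.3 kcal/mol."""
    return make_reaction_surface(7.8, -10.3)


@pytest.fixture(scope="session")
def surface_78_truth(surface_78):
    return surface_ground_truth(surface_78)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
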