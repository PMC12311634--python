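import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrqa import synth

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: compact complex used throughout the suite; every in-scope computation
#: only needs backbone atoms, so small chains exercise the same code paths
TINY_LENGTHS = {"TCRA": 16, "TCRB": 16, "PEP": 8, "MHC": 20}
CHAIN_MAP = {"D": "TCRA", "E": "TCRB", "C": "PEP", "A": "MHC"}


@pytest.fixture(scope="session")
def native():
    return synth.make_native("fix0", TINY_LENGTHS, seed=11)


@pytest.fixture(scope="session")
def decoy_pool(native):
    recipes = synth.default_recipes(24, seed=5)
    return synth.make_decoys(native, recipes)


def random_rigid(rng):
    """A uniformly random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=15.0, size=3)
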