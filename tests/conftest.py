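import numpy as np
import pytest

from wormyield import (
    EffectParams,
    Grid,
    GridTransform,
    WorldConfig,
    derive_all_coefficients,
    load_effect_table,
)
from wormyield.synth import generate_with_truth, generate_world


@pytest.fixture(scope="session")
def effect_table():
    return load_effect_table()


@pytest.fixture(scope="session")
def coefs(effect_table):
    return derive_all_coefficients(effect_table)


@pytest.fixture(scope="session")
def params():
    return EffectParams.from_effect_table()


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(shape=(30, 30), seed=11))


@pytest.fixture(scope="session")
def truth_world():
    return generate_with_truth(WorldConfig(shape=(40, 40), seed=5))


def make_grid(values, mask=None, cell=5.0):
    return Grid(values=np.asarray(values, dtype=float),
                transform=GridTransform(cell_arcmin=cell), mask=mask)
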