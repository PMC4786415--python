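"""Shared fixtures: synthetic bundles are generated once per session."""

import numpy as np
import pytest

from betalayer.synthetic import (
    CrickParams,
    generate_beta_layer_fixture,
    generate_crick_coil,
)


@pytest.fixture(scope="session")
def nonad_fixture():
    return generate_beta_layer_fixture("nonad", seed=0)


@pytest.fixture(scope="session")
def hexad_fixture():
    return generate_beta_layer_fixture("hexad", seed=0)


@pytest.fixture(scope="session")
def tandem_fixture():
    return generate_beta_layer_fixture("tandem-hexad", seed=0)


@pytest.fixture(scope="session")
def heptad_coil():
    return generate_crick_coil(CrickParams(supercoil_periodicity=3.5), 28)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniform random rotation plus a bounded random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rng.uniform(-50.0, 50.0, size=3)
    return rotation, translation
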