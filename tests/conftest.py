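import numpy as np
import pytest

import stainfit as sf


@pytest.fixture(scope="session")
def default_case() -> sf.SyntheticCase:
    """The canonical two-body benchmark case (noiseless, seed 7)."""
    return sf.make_two_body_case()


@pytest.fixture(scope="session")
def toy_chain() -> sf.AtomicModel:
    return sf.make_toy_chain(60, helical_fraction=0.8, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def small_map(rng) -> sf.DensityMap:
    return sf.DensityMap(values=rng.random((6, 5, 4)), voxel_size=[1.0, 1.5, 2.0],
                         origin=[-10.0, 5.0, 0.0], label="toy")
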