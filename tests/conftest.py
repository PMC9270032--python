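import numpy as np
import pytest

from cnscensus.core import PointCloud, Sex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    return PointCloud(animal_id="A1", line="brp", sex=Sex.FEMALE,
                      points=rng.uniform(0, 10, (30, 3)))


@pytest.fixture
def two_animal_clouds(rng):
    return [
        PointCloud("A1", "brp", Sex.FEMALE, rng.uniform(0, 10, (20, 3))),
        PointCloud("B2", "repo", Sex.MALE, rng.uniform(0, 10, (15, 3))),
    ]
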