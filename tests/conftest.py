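import numpy as np
import pytest

from leafseg.synthetic import PlantSpec, apply_sensor_effects, make_plant


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_plant():
    """A labeled five-leaf plant with sensor effects, ~650 points."""
    spec = PlantSpec(leaf_count=5, seed=3)
    return apply_sensor_effects(make_plant(spec), spec)


@pytest.fixture(scope="session")
def clean_plant():
    """A labeled plant without noise/thinning (exact analytic normals)."""
    return make_plant(PlantSpec(leaf_count=4, seed=7))
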