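import numpy as np
import pytest

from msom.phantom import Absorber, AbsorberScene, box_domain


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_sphere_scene():
    """One broadband 20 um microsphere at the scan centre."""
    return AbsorberScene(
        [Absorber((0.0, 0.0, 0.0), 10.0, {"black": 1.0})],
        box_domain((8000.0, 8000.0, 8000.0)),
    )
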