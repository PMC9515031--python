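import numpy as np
import pytest

from hipcart.geometry import frame_from_mask
from hipcart.phantom import PhantomTruth, make_shell_phantom


@pytest.fixture(scope="session")
def lunate_phantom():
    """Lunate patch phantom at 1 mm spacing with its fitted sphere/frame."""
    truth = PhantomTruth(
        centre=(2.0, -1.0, 3.0),
        r_inner=42.5,
        r_outer=45.5,
        polar_range=(20.0, 110.0),
        azimuth_range=(-80.0, 80.0),
    )
    t1_map, mask, truth = make_shell_phantom(truth, spacing=(1.0, 1.0, 1.0))
    sphere, frame = frame_from_mask(mask)
    return t1_map, mask, truth, sphere, frame


@pytest.fixture(scope="session")
def full_shell_phantom():
    """Full spherical shell (r 42.5-45.5 mm) at 0.5 mm spacing."""
    truth = PhantomTruth(r_inner=42.5, r_outer=45.5)
    t1_map, mask, truth = make_shell_phantom(truth, spacing=(0.5, 0.5, 0.5))
    return t1_map, mask, truth


def random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
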