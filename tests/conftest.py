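"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from ablaquant.elasticity import MaterialParams
from ablaquant.imaging_io import LabelMap, VolumeImage
from ablaquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature pelvic scene (48 mm FOV) for fast unit tests."""
    return PhantomSpec(
        field_of_view=(48.0, 48.0, 48.0),
        prostate_center=(24.0, 24.0, 20.0),
        prostate_axes=(8.0, 7.0, 7.0),
        bladder_center=(24.0, 32.0, 32.0),
        bladder_axes=(7.0, 6.0, 6.0),
        rectum_center_xy=(24.0, 11.0),
        rectum_radius=4.0,
        rectum_z_range=(6.0, 40.0),
        rectum_bend_mm=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture(scope="session")
def compact_spec():
    return PhantomSpec.compact(seed=11)


@pytest.fixture(scope="session")
def compact_phantom(compact_spec):
    return generate_phantom(compact_spec)


@pytest.fixture(scope="session")
def soft_tissue():
    return MaterialParams(30.0, 0.45)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def cube_labels():
    """A 10 mm cube organ centred in a 12^3 grid at 1 mm spacing."""
    lab = np.zeros((12, 12, 12), dtype=np.int32)
    lab[1:11, 1:11, 1:11] = 1
    return LabelMap(lab)


@pytest.fixture()
def noise_volume(rng):
    return VolumeImage(rng.normal(100.0, 10.0, size=(16, 16, 16)),
                       (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
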