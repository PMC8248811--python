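"""Shared fixtures: small random images and phantom specifications."""

import numpy as np
import pytest

from mcatlas.images import Channel, ChannelSet, MaskImage, ScalarImage, SHImage
from mcatlas.phantom import PhantomSpec, template_truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_sh_pair(rng):
    """Two random 8^3 SH images with lmax 2 on a shared grid."""
    a = SHImage(rng.standard_normal((8, 8, 8, 6)), 2)
    b = SHImage(rng.standard_normal((8, 8, 8, 6)), 2)
    return a, b


@pytest.fixture()
def small_scalar_pair(rng):
    a = ScalarImage(rng.standard_normal((8, 8, 8)))
    b = ScalarImage(rng.standard_normal((8, 8, 8)))
    return a, b


@pytest.fixture(scope="session")
def tiny_spec():
    """A 24^3 noiseless phantom used by the heavier integration tests."""
    return PhantomSpec(grid_shape=(24, 24, 24), noise_sigma=0.0, warp_amplitude_voxels=0.0)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return template_truth(tiny_spec)


def make_channelset(images: dict, roles: dict, subject_id="s", age=40.0) -> ChannelSet:
    return ChannelSet(
        subject_id, age, [Channel(n, img, roles[n]) for n, img in images.items()]
    )
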