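"""Shared fixtures: small phantoms and tiny networks sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from clickseg.networks import NetworkConfig, build_network
from clickseg.phantoms import PhantomSpec, generate_dataset, generate_phantom


TINY_SPEC = PhantomSpec(
    shape=(16, 16, 16),
    tumor_radius_range=(2.5, 4.0),
    distractor_count=1,
    distractor_radius_range=(1.2, 2.0),
    seed=11,
)

SMALL_SPEC = PhantomSpec(
    shape=(32, 32, 32),
    tumor_radius_range=(5.0, 8.0),
    distractor_count=2,
    distractor_radius_range=(2.0, 3.0),
    seed=12,
)


def tiny_net_cfg(in_channels: int) -> NetworkConfig:
    return NetworkConfig(in_channels=in_channels, channels=(4, 8), strides=(1, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_phantom():
    return generate_phantom(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(6, TINY_SPEC, seed=5)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def tiny_nets():
    """Random-weight tiny initial/refinement/baseline networks (16^3-ready)."""
    return {
        2: build_network(tiny_net_cfg(2), seed=1),
        4: build_network(tiny_net_cfg(4), seed=2),
        5: build_network(tiny_net_cfg(5), seed=3),
    }


def random_mask(rng: np.random.Generator, shape=(16, 16, 16), p: float = 0.15):
    """A random blobby non-empty mask: thresholded smoothed noise."""
    from scipy import ndimage
    from clickseg.volumes import BinaryMask

    while True:
        x = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        m = x > np.quantile(x, 1.0 - p)
        if m.any():
            return BinaryMask(m.astype(np.uint8))
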