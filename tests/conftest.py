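"""Shared fixtures: phantoms are generated once per session where possible."""

from __future__ import annotations

import numpy as np
import pytest

from pancmotion.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom with masks and ground truth only (no MR intensity)."""
    return generate_phantom(PhantomConfig(seed=1), with_intensity=False)


@pytest.fixture(scope="session")
def default_masks(default_phantom):
    return default_phantom.masks


def three_spheres(shape=(48, 20, 20), radius=4.0,
                  centers=((8, 10, 10), (24, 10, 10), (40, 10, 10))):
    """Binary map of three well-separated spheres plus per-sphere labels."""
    grid = np.indices(shape).astype(float) + 0.5
    mask = np.zeros(shape, dtype=bool)
    membership = np.zeros(shape, dtype=int)
    for code, c in enumerate(centers, start=1):
        d2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
        sph = d2 <= radius**2
        mask |= sph
        membership[sph] = code
    return mask, membership
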