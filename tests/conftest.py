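import numpy as np
import pytest

from surfelseg import Image3D, Params


@pytest.fixture
def params():
    """Default parameter set used throughout: d0 = 3 px."""
    return Params(d0=3.0, rng_seed=0)


@pytest.fixture
def flat_image():
    """A featureless volume: image forces reduce to the pressure term."""
    return Image3D(np.zeros((60, 60, 60)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_radius(positions, center, radius, exclude=None):
    """O(n^2)-style oracle for fixed-radius queries (closed ball)."""
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions - np.asarray(center, dtype=float), axis=1)
    idx = np.nonzero(d <= radius + 1e-12)[0]
    if exclude is not None:
        idx = idx[idx != exclude]
    return set(int(i) for i in idx)


def hex_patch(d0, object_id=0):
    """A 7-surfel flat hexagonal patch at spacing d0, normals +z.

    The central surfel sits at the origin; by symmetry the net pair force
    and torque on it vanish.
    """
    from surfelseg import make_surfel

    surfels = [make_surfel((0, 0, 0), (0, 0, 1), object_id)]
    for k in range(6):
        a = np.pi / 3 * k
        surfels.append(
            make_surfel((d0 * np.cos(a), d0 * np.sin(a), 0.0), (0, 0, 1), object_id)
        )
    return surfels
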