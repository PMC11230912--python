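import numpy as np
import pytest

from condkit import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_disks(rng, n, shape, r_range=(5.0, 20.0), gap=2.0, max_tries=5000):
    """Rejection-sample n non-overlapping disks fully inside the frame."""
    ny, nx = shape
    centers, radii = [], []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = float(rng.uniform(*r_range))
        x = float(rng.uniform(r + 1, nx - r - 2))
        y = float(rng.uniform(r + 1, ny - r - 2))
        if all(
            np.hypot(x - cx, y - cy) >= r + cr + gap
            for (cx, cy), cr in zip(centers, radii)
        ):
            centers.append((x, y))
            radii.append(r)
    assert len(centers) == n, "could not place the requested disks"
    return centers, radii


@pytest.fixture
def five_disk_truth():
    return synthgen.DropletFieldTruth(
        centers=[(30, 30), (90, 30), (30, 90), (90, 90), (60, 60)],
        radii=[8, 10, 9, 11, 7],
        dilute_level=10.0,
        dense_level=100.0,
        shape=(128, 128),
        seed=7,
    )
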