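import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from voronoitrack.phantom import (  # noqa: E402
    PhantomSpec,
    round_centerline,
    simulate_centerline,
    voxelize_union_of_spheres,
)


@pytest.fixture(scope="session")
def capsule_ref():
    """Straight constant-radius vessel: its exact medial axis is the segment."""
    spec = PhantomSpec(
        "BRANCH", length=20.0, radius_start=1.0, radius_end=1.0, tortuosity=0.0
    )
    return round_centerline(simulate_centerline(spec))


@pytest.fixture(scope="session")
def capsule_vol(capsule_ref):
    return voxelize_union_of_spheres(capsule_ref, voxel_size=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)


def random_blob(rng, size=48, sigma=6.0):
    """Random smooth binary blob for skeleton property tests."""
    from scipy import ndimage

    noise = rng.normal(size=(size, size))
    smooth = ndimage.gaussian_filter(noise, sigma)
    mask = (smooth > np.quantile(smooth, 0.7)).astype(np.uint8)
    # keep the largest component to avoid dust
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
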