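import numpy as np
import pytest

import vregnet3d as v


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small noisy phantom with well-separated nuclei, shared across tests."""
    spec = v.PhantomSpec(
        shape_voxels=(48, 48, 24), voxel_size_um=(1.0, 1.0, 1.0),
        nucleus_radius_range_um=(2.2, 3.2), eccentricity_range=(1.1, 1.5),
        n_nuclei=8, min_center_spacing_um=8.0,
        psf_sigma_um=(0.5, 0.5, 1.0), gaussian_sd=0.02, poisson_scale=400.0,
        attenuation_per_um=0.002, speckle_fraction=0.1, seed=11)
    return v.generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_label_volume(rng, shape=(16, 16, 16), n_blobs=4):
    """Random non-touching-ish blob labels for oracle comparisons."""
    lab = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_blobs + 1):
        c = rng.integers(2, np.asarray(shape) - 2)
        r = rng.integers(1, 4)
        g = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum((gi - ci) ** 2 for gi, ci in zip(g, c))
        lab[d2 <= r ** 2] = k
    return lab
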