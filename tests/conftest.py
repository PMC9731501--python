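import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default noisy phantom, shared across tests (read-only)."""
    from diffseg.phantom import make_phantom

    return make_phantom(seed=1)


@pytest.fixture(scope="session")
def phantom_noise_free():
    from diffseg.phantom import make_phantom

    return make_phantom(seed=1, noisy=False)


def random_mask(rng, shape=(20, 20, 20), p=0.5):
    from diffseg.image import BinaryMask

    return BinaryMask(rng.random(shape) < p, np.eye(4))


def brute_force_erode(data: np.ndarray) -> np.ndarray:
    """Exhaustive per-voxel 3x3x3 neighbourhood scan (oracle)."""
    padded = np.pad(data, 1, constant_values=False)
    out = np.zeros_like(data)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = padded[i:i + 3, j:j + 3, k:k + 3].all()
    return out


def brute_force_dilate(data: np.ndarray) -> np.ndarray:
    padded = np.pad(data, 1, constant_values=False)
    out = np.zeros_like(data)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = padded[i:i + 3, j:j + 3, k:k + 3].any()
    return out
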