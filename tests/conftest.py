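import numpy as np
import pytest

import soilct as sc


@pytest.fixture(scope="session")
def scheme():
    return sc.default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_core():
    """Deterministic (20, 32, 32) synthetic core with ground truth."""
    spec = sc.soil_core_spec(seed=7, extents=(20, 32, 32))
    return sc.generate_volume(spec)


def random_volume(rng, extents=(8, 16, 16), lo=0, hi=6144):
    voxels = rng.integers(lo, hi + 1, size=extents)
    return sc.CTVolume(voxels, sample_id="random")


def best_constant_rmse(targets: np.ndarray) -> float:
    """RMSE of the best constant predictor (the mean): the std."""
    targets = np.asarray(targets, dtype=float)
    return float(np.sqrt(np.mean((targets - targets.mean()) ** 2)))
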