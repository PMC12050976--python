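import numpy as np
import pytest

from ziqsir import DGPConfig, Dataset, FitConfig, gen_dataset

# reduced optimizer budget shared by the heavier statistical tests
FAST_FIT = FitConfig(n_starts=3, max_outer_evals=60)


@pytest.fixture(scope="session")
def alt_dataset_500():
    """One Setting-1 alternative dataset at n=500 with x1 tested."""
    sim = gen_dataset(DGPConfig(setting=1, n=500, seed=20240917))
    return sim.to_dataset((1,))


@pytest.fixture(scope="session")
def null_fit_500(alt_dataset_500):
    """Median-level null fit on the shared dataset (batch optimizer budget)."""
    from ziqsir import fit_null

    return fit_null(alt_dataset_500, 0.5, FAST_FIT)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n=200, p=1, q=3, zero_frac=0.3):
    """Small generic zero-inflated dataset for unit tests."""
    Z = rng.standard_normal((n, p))
    C = rng.standard_normal((n, q))
    Y = np.abs(rng.standard_normal(n)) + 0.5
    Y[rng.random(n) < zero_frac] = 0.0
    return Dataset(Y=Y, Z=Z, C=C)
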