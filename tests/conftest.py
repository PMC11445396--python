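import numpy as np
import pytest

from spatialcov import compute_covet, simulate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    return simulate_tissue(n_cells=256, G_full=30, G_panel=20, seed=7)


@pytest.fixture(scope="session")
def small_covet(small_tissue):
    return compute_covet(small_tissue.counts_panel, small_tissue.coords, k=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_psd(rng, g, n=None):
    """Random Gramian PSD matrices: X X^T with standard-normal X."""
    if n is None:
        X = rng.standard_normal((g, g))
        return X @ X.T
    X = rng.standard_normal((n, g, g))
    return X @ np.swapaxes(X, -1, -2)
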