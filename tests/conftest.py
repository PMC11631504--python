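import numpy as np
import pytest

from ridgepath import simulate_genotypes, simulate_phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_dataset():
    """p >> n marker panel with a moderately heritable polygenic trait."""
    X = simulate_genotypes(60, 200, seed=101)
    y, truth = simulate_phenotype(X, n_qtl=30, h2_target=0.5, seed=102)
    return X, y, truth


@pytest.fixture
def standardized_small(small_dataset):
    from ridgepath import fit_standardizer, transform

    X, y, _ = small_dataset
    stats = fit_standardizer(X, y)
    Xs, ys = transform(X, y, stats=stats)
    return Xs, ys
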