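import numpy as np
import pandas as pd
import pytest

from autoppi import (UniverseConfig, generate_universe, gaussian_feature_spec,
                     generate_feature_dataset)


@pytest.fixture(scope="session")
def small_universe():
    """A compact synthetic universe for feature / gold-standard tests."""
    cfg = UniverseConfig(n_proteins=120, n_go_terms=60, n_kegg_terms=20,
                         n_samples=40, n_planted=40, seed=5)
    return generate_universe(cfg)


@pytest.fixture(scope="session")
def gaussian_table():
    """Feature-level table from the single-Gaussian benchmark spec."""
    spec = gaussian_feature_spec(mu_pos=1.0, mu_neg=0.0, sigma=1.0)
    return spec, generate_feature_dataset(spec, 2000, 2000, seed=42)


@pytest.fixture()
def random_feature_table():
    """A 200-row random continuous table for split-search oracles."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=1.5, size=200) > 0).astype(int)
    return X, y
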