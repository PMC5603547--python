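import numpy as np
import pandas as pd
import pytest

from lncnet import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the generator at its documented defaults."""
    return simulate_experiment(SimConfig(seed=7))


@pytest.fixture()
def small_counts():
    """Tiny hand-checkable count matrix, 4 genes x 4 samples."""
    return pd.DataFrame(
        {
            "s1": [10, 20, 5, 0],
            "s2": [12, 18, 6, 0],
            "s3": [9, 22, 4, 0],
            "s4": [11, 19, 5, 0],
        },
        index=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture()
def nb_null_counts():
    """NB counts with no group difference: 2000 genes, 4+4, phi = 0.2."""
    rng = np.random.default_rng(101)
    n_genes, phi = 2000, 0.2
    mu = rng.lognormal(3.5, 1.0, n_genes)
    s = rng.uniform(0.7, 1.3, 8)
    mean = mu[:, None] * s[None, :]
    lam = rng.gamma(1 / phi, phi * mean)
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(8)],
    )
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
    return counts, groups
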