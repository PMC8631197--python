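import numpy as np
import pandas as pd
import pytest

from cernapipe.config import SimConfig
from cernapipe.containers import CountMatrix
from cernapipe.simulate import simulate_experiment


SMALL_SIM = dict(n_mrna=120, n_lncrna=50, n_circrna=40, n_mirna=60,
                 n_planted_triplets=8, n_shared_mrnas=2)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic experiment (the generator's defaults)."""
    return simulate_experiment(SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced experiment for fast structural tests."""
    return simulate_experiment(SimConfig(rng_seed=5, **SMALL_SIM))


@pytest.fixture()
def toy_counts():
    """3 features x 2 samples with lengths, for arithmetic oracles."""
    values = pd.DataFrame([[10, 20], [100, 50], [0, 5]],
                          index=pd.Index(["f1", "f2", "f3"],
                                         name="feature_id"),
                          columns=["s1", "s2"])
    lengths = pd.Series([1000, 500, 2000], index=values.index)
    return CountMatrix(values, "mRNA", lengths)


def nb_counts(rng, mu, alpha, size):
    """Draw NB(mu, alpha) counts with variance mu + alpha*mu^2."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)
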