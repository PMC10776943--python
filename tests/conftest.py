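import numpy as np
import pandas as pd
import pytest

from soilrisk import synthetic
from soilrisk.core import METALS, ConcentrationTable


@pytest.fixture(scope="session")
def default_dataset():
    """Default three-source synthetic survey, fixed seed."""
    return synthetic.generate(n_sites=30, seed=20230)


@pytest.fixture(scope="session")
def lowrank_dataset():
    """Noise-free, background-free rank-3 survey for factorization tests."""
    return synthetic.generate(n_sites=30, seed=11, noise_cv=0.0,
                              background=None,
                              sources=synthetic.default_sources(30, None))


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.uniform(1, 10, (6, 8)),
                      index=[f"S{i}" for i in range(6)], columns=list(METALS))
    return ConcentrationTable(df)
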