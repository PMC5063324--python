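import numpy as np
import pytest

import svclake as sl


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic lake table small enough for fast MCMC, with truth record."""
    cfg = sl.SimConfig(n_sites=40, repeat_mean_extra=6.0)
    df, truth = sl.generate_dataset(cfg, np.random.default_rng(7))
    return cfg, df, truth


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    _, df, _ = small_dataset
    return sl.build_model_frame(df)


@pytest.fixture(scope="session")
def small_fit(small_frame):
    """A short but usable SVC fit shared across read-only tests."""
    return sl.SVCModel(small_frame).fit(n_iter=800, n_burn=400, n_thin=2, seed=5)
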