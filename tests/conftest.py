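import numpy as np
import pytest

from sdgae.data_io import RunConfig
from sdgae.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def tiny_ds():
    """Small clustered dataset for fast structural tests."""
    return generate(SynthConfig(m=20, n=30, c=3, n_diseases=12,
                                n_sideeffects=9, seed=1))


@pytest.fixture(scope="session")
def bench_ds():
    """The default desk-scale benchmark (60 drugs x 80 targets, 4 clusters)."""
    return generate(SynthConfig())


@pytest.fixture
def fast_cfg():
    """Config small enough for seconds-scale training in unit tests."""
    return RunConfig.desk_profile(hidden_dim=32, embed_dim=16, epochs=40,
                                  n_estimators=60, n_folds=3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
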