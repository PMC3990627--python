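import numpy as np
import pytest

from reprotraj import io, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One ~170-cell dataset under the packaged default study conditions."""
    cfg = simulate.default_config(seed=11)
    ct, ann, truth = simulate.generate_dataset(cfg)
    return cfg, ct, ann, truth


@pytest.fixture(scope="session")
def qc_passed_matrix(default_dataset):
    _, ct, ann, _ = default_dataset
    m = io.ExpressionMatrix(ct, ann)
    m, _ = io.qc_filter(m)
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20140417)
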