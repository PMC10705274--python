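import numpy as np
import pytest

import mesoplast as mp


@pytest.fixture(scope="session")
def atlas():
    return mp.default_atlas()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-effect cohort at reduced size (6 subjects/group)."""
    cfg = mp.SyntheticConfig(n_subjects_per_group=6, seed=42)
    return cfg, mp.generate_group_dataset(cfg)


@pytest.fixture(scope="session")
def single_node_sc():
    return mp.StructuralConnectome(weights=np.zeros((1, 1)))


@pytest.fixture(scope="session")
def random_fc(rng):
    """A random valid 90-node FC matrix."""
    x = rng.standard_normal((120, 90))
    fc = np.corrcoef(x.T)
    np.fill_diagonal(fc, 1.0)
    return mp.FunctionalConnectome(values=fc)


def random_symmetric_fc(n, rng):
    x = rng.standard_normal((4 * n, n))
    fc = np.corrcoef(x.T)
    np.fill_diagonal(fc, 1.0)
    return fc
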