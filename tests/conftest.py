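import numpy as np
import pandas as pd
import pytest

from dyadmap import SimConfig, make_genome, simulate_mnase_pairs


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """Default two-chromosome mini-genome at a fixed seed."""
    return make_genome(default_config)


@pytest.fixture(scope="session")
def wt_pairs(bundle):
    return simulate_mnase_pairs(bundle, "wt")


@pytest.fixture(scope="session")
def mut_pairs(bundle):
    return simulate_mnase_pairs(bundle, "mutant")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_pairs(chroms, left5s, isizes):
    return pd.DataFrame(
        {"chrom": chroms, "left5": np.asarray(left5s, dtype=np.int64),
         "isize": np.asarray(isizes, dtype=np.int64)}
    )
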