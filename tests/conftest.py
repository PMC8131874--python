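import numpy as np
import pandas as pd
import pytest

from crosshub.genome import ChromSizes, make_bins
from crosshub.simulate import SimConfig


@pytest.fixture
def toy_sizes():
    return ChromSizes([("chr1", 2_000_000), ("chr2", 1_000_000), ("chrX", 500_000)])


@pytest.fixture
def toy_bins(toy_sizes):
    return make_bins(toy_sizes, 1_000_000)


@pytest.fixture
def small_cfg():
    """Reduced genome for fast end-to-end runs."""
    return SimConfig(n_chroms=4, chrom_length=4_000_000, mu0_intra=15.0,
                     mu0_inter=80.0, n_hub_pairs=6, n_intra_diff_pairs=5, seed=11)


@pytest.fixture
def counts_2x2():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.poisson(100, size=(50, 4)),
                      columns=["EE1", "EE2", "CTL1", "CTL2"],
                      index=[f"f{i}" for i in range(50)])
    groups = {"EE1": "EE", "EE2": "EE", "CTL1": "CTL", "CTL2": "CTL"}
    return df, groups
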