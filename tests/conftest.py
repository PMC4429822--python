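import pandas as pd
import pytest

import dhs_atlas as da


@pytest.fixture(scope="session")
def tiny_config():
    """Small synthetic genome: 1 x 200 kb, 40 planted DHSs, 50 k tags."""
    return da.SimConfig(
        n_chroms=1, chrom_length=200_000, n_true_dhs=40, depth=50_000, seed=11
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_config):
    return da.simulate_truth(tiny_config)


@pytest.fixture(scope="session")
def tiny_tags(tiny_config, tiny_truth):
    ts, _ = da.simulate_tags(tiny_config, "P0", truth=tiny_truth)
    return ts


@pytest.fixture(scope="session")
def tiny_mappable(tiny_config):
    return pd.DataFrame(
        [(c, 0, l) for c, l in tiny_config.genome.items()],
        columns=["chrom", "start", "end"],
    )
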