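import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from occmeth import MethylationMatrix, SimConfig, simulate_beta_matrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


SMALL_GROUPS = {"tumor_mt": 6, "tumor_wt": 6, "cell_mt": 6, "cell_wt": 6, "ko_pairs": 2}


@pytest.fixture
def small_config() -> SimConfig:
    """A fast, fully structured simulation for unit tests."""
    return SimConfig(
        n_probes=1000,
        n_genes=200,
        samples_per_group=dict(SMALL_GROUPS),
        planted_set_size=3,
        n_candidates=1,
        seed=7,
    )


@pytest.fixture
def small_sim(small_config):
    meth, truth = simulate_beta_matrix(small_config)
    return small_config, meth, truth


@pytest.fixture
def tiny_matrix() -> MethylationMatrix:
    """A deterministic 6-probe x 4-sample matrix for transform/filter tests."""
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(6, 4)),
        index=[f"cg{i}" for i in range(6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    return MethylationMatrix(beta)
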