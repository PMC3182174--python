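import numpy as np
import pandas as pd
import pytest

from fatbody import Design, SimConfig, simulate_count_matrix


@pytest.fixture(scope="session")
def small_count_sim():
    cfg = SimConfig(seed=101, n_proteins=60, n_replicates=5)
    return simulate_count_matrix(cfg)


@pytest.fixture(scope="session")
def null_count_sim():
    cfg = SimConfig(
        seed=102,
        n_proteins=150,
        n_replicates=5,
        frac_genotype_effect=0.0,
        frac_treatment_effect=0.0,
        frac_age_effect=0.0,
    )
    return simulate_count_matrix(cfg)


@pytest.fixture()
def four_group_design():
    return Design.from_groups(n_replicates=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
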