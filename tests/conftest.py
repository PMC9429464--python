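import numpy as np
import pytest

from mlsem import (ITEM_NAMES, default_config, generate_households,
                   polychoric_matrix)


@pytest.fixture(scope="session")
def study_dataset():
    """Survey-scale synthetic dataset at the default study conditions."""
    return generate_households(default_config(n_households=888, seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Small dataset for fast structural-model tests."""
    return generate_households(default_config(n_households=80, seed=9))


@pytest.fixture(scope="session")
def null_structural_dataset():
    """Dataset with no structural part: eta ~ N(0, psi_ind + psi_hh)."""
    cfg = default_config(n_households=2000, seed=5,
                         beta=np.zeros(8), gamma=np.zeros(2),
                         psi_ind=0.015, psi_hh=0.005)
    return generate_households(cfg)


@pytest.fixture(scope="session")
def study_polymat(study_dataset):
    return polychoric_matrix(study_dataset.df[ITEM_NAMES])
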