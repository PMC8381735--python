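import numpy as np
import pytest

from lncpairsig.syndata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that still carries every planted signal."""
    return SimConfig(
        n_tumor=250,
        n_normal=30,
        n_lnc=60,
        n_imm=30,
        n_coexpr=20,
        n_de=12,
        n_true_pairs=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
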