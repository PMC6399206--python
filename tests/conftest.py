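import numpy as np
import pytest

from fcage import connectome as cn
from fcage import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural/unit checks (not for recovery power)."""
    cfg = syn.default_config(n_subjects=24, n_nodes=12, n_volumes=160, seed=3)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition internal cohort (seed 7, n=200, p=50)."""
    return syn.generate_cohort(syn.default_config(seed=7))


@pytest.fixture(scope="session")
def default_cohort_edges(default_cohort):
    return cn.build_cohort_matrix(default_cohort)


@pytest.fixture(scope="session")
def paired_cohorts():
    """Default internal/external pair with shared planted structure."""
    cfg_int, cfg_ext = syn.default_paired_configs(seed=7)
    return syn.generate_paired_cohorts(cfg_int, cfg_ext, shared_truth=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
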