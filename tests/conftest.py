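import numpy as np
import pytest

from restpred.core import RestScan
from restpred.synthetic import SimConfig, make_geometry, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(
        n_subjects=12,
        n_total=60,
        n_cortex=50,
        t_per_run=60,
        n_runs=2,
        n_latent=4,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config, K=6)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_config):
    return make_geometry(tiny_config)


def make_preprocessed_scan(rng, n_total, t, subject_id="sub"):
    """Random scan that already satisfies the preprocessing contract."""
    x = rng.standard_normal((n_total, t))
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return RestScan(subject_id=subject_id, data=x, run_boundaries=[t], preprocessed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
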