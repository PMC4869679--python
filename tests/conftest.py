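import numpy as np
import pytest

from betarousal.config import McmcConfig, PipelineConfig
from betarousal.synthetic import SubjectProfile, simulate_study


@pytest.fixture(scope="session")
def fast_mcmc():
    """Small but converged sampler profile for unit tests."""
    return McmcConfig(n_chains=4, n_iter=600, burn_in=300)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Six clean subjects at reduced sampling rates: seconds, not minutes."""
    cfg = PipelineConfig(seed=11)
    cfg.cohort.n_subjects = 6
    cfg.cohort.n_corrupt_eda = 0
    cfg.cohort.n_corrupt_hr = 0
    cfg.signal.eda_fs = 25.0
    cfg.signal.hr_fs = 5.0
    cfg.mcmc = McmcConfig(n_chains=4, n_iter=400, burn_in=200)
    return cfg


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    return simulate_study(cfg=tiny_cfg, seed=tiny_cfg.seed)


@pytest.fixture(scope="session")
def default_cfg():
    """The full study conditions: 68 subjects, 4/5 corrupted channels."""
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def default_study(default_cfg):
    return simulate_study(cfg=default_cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def neutral_profile():
    return SubjectProfile(subject_id="S1", gender="female", bis=21, bas=39,
                          nonplanning=22, latent_reactivity=0.0,
                          latent_bet_bias=0.0)
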