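import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluorsense import simulate
from fluorsense.config import ImagingParams, SimulationConfig, paper_preset
from fluorsense.spectral import normalize_to_baseline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_cfg():
    """Study-faithful configuration, seed 1."""
    return paper_preset(1)


@pytest.fixture(scope="session")
def nf_cfg(paper_cfg):
    """Paper preset with every noise source zeroed."""
    return paper_cfg.without_noise()


@pytest.fixture(scope="session")
def nf_series(nf_cfg):
    return simulate.simulate_reflectance_series(nf_cfg)


@pytest.fixture(scope="session")
def nf_norm(nf_series):
    return normalize_to_baseline(nf_series)


@pytest.fixture(scope="session")
def nf_phi(nf_cfg):
    return simulate.simulate_phipsii_timecourse(nf_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """Cheap config for image-stack tests: small frame, no noise."""
    return SimulationConfig(
        seed=5, imaging=ImagingParams(shape=(96, 128))
    ).without_noise()


@pytest.fixture(scope="session")
def small_stack(small_cfg):
    return simulate.simulate_cfi_stack(small_cfg)


@pytest.fixture(scope="session")
def nf_default_stack(nf_cfg):
    """Noise-free stack at the full study geometry (shared: it is slow)."""
    return simulate.simulate_cfi_stack(nf_cfg)


@pytest.fixture(scope="session")
def nf_relaxation(nf_cfg):
    return simulate.simulate_npq_relaxation(nf_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
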