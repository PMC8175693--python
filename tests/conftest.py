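import pytest
from hypothesis import HealthCheck, settings

from fishbone.engine import SimulationConfig, run_sweep

settings.register_profile(
    "fishbone",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fishbone")


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Study-scale configuration: 800 ms scans at dt = 0.01 ms, 5 finger samples."""
    return SimulationConfig(n_samples=5, master_seed=1)


@pytest.fixture(scope="session")
def pm1_sweep(study_config):
    """Full PM1 sweep over the nine experimental rib intervals (5 samples)."""
    return run_sweep(study_config, matrices=("PM1",))


@pytest.fixture(scope="session")
def pm2_sweep(study_config):
    """Full PM2 sweep over the nine experimental rib intervals (5 samples)."""
    return run_sweep(study_config, matrices=("PM2",))


@pytest.fixture()
def quick_config() -> SimulationConfig:
    """Short-window configuration for fast engine plumbing tests."""
    return SimulationConfig(n_samples=1, master_seed=7, T=100.0)
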