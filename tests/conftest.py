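import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def g0():
    from beamforge import default_spectrum_6mv

    return default_spectrum_6mv()


@pytest.fixture(scope="session")
def fast_config():
    """Small-history engine configuration for wiring-level tests."""
    from beamforge import EngineConfig

    return EngineConfig(seed=7, n_photons=60_000, n_electrons=20_000, n_batches=5)


@pytest.fixture(scope="session")
def water_forward_fast(fast_config):
    from beamforge.forward import WaterForwardModel
    from beamforge.types import MachineMeta

    return WaterForwardModel(MachineMeta(), fast_config)


@pytest.fixture(scope="session")
def closed_loop_result():
    """Full-scale golden-machine commissioning loop (shared by the
    acceptance tests; runs several minutes)."""
    from beamforge.closedloop import run_closed_loop

    return run_closed_loop(seed=1)


def two_bin_spectrum():
    from beamforge import EnergySpectrum

    return EnergySpectrum(np.array([1.0, 3.0]), np.array([0.5, 0.5]))
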