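import numpy as np
import pytest

from iemgbench import (
    DriftConfig,
    NetConfig,
    SimConfig,
    WindowingConfig,
)


@pytest.fixture(scope="session")
def sim_default() -> SimConfig:
    """Default study conditions with a fixed subject seed."""
    return SimConfig(seed=123)


@pytest.fixture(scope="session")
def sim_nodrift() -> SimConfig:
    """All drift sources switched off (still has repetition jitter)."""
    return SimConfig(
        day_drift=DriftConfig(),
        session_drift=DriftConfig(),
        session_gain_trend=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def sim_frozen() -> SimConfig:
    """Fully deterministic amplitudes: no drift and no repetition jitter."""
    return SimConfig(
        day_drift=DriftConfig(),
        session_drift=DriftConfig(),
        session_gain_trend=0.0,
        repetition_jitter_std=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def wcfg() -> WindowingConfig:
    return WindowingConfig()


@pytest.fixture(scope="session")
def wcfg_abs() -> WindowingConfig:
    """Absolute-threshold windowing for reproducibility-style checks."""
    return WindowingConfig(epsilon_mode="absolute", epsilon_value=0.01)


@pytest.fixture(scope="session")
def netcfg() -> NetConfig:
    return NetConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
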