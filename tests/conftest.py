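import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import photocr as p

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cal() -> p.CalibrationModel:
    """Factory calibration: through-origin cubic on the three printed triples."""
    return p.default_calibration()


@pytest.fixture(scope="session")
def short_program() -> p.LightProgram:
    """A scaled-down trapezoid for fast closed-loop tests."""
    return p.LightProgram(rise_s=600.0, plateau_s=300.0, fall_s=600.0,
                          n_ramps=2, lead_in_s=120.0)


@pytest.fixture(scope="session")
def quiet_config(short_program, cal) -> p.SimulationConfig:
    """Noise-free study conditions on the short program."""
    return p.SimulationConfig(program=short_program, calibration=cal,
                              sigma_heat_W=0.0, sigma_o2_pct=0.0)


@pytest.fixture(scope="session")
def quiet_run(quiet_config) -> p.SimulationRun:
    return p.simulate_run(quiet_config, seed=1)


@pytest.fixture(scope="session")
def noisy_run(short_program, cal) -> p.SimulationRun:
    cfg = p.SimulationConfig(program=short_program, calibration=cal)
    return p.simulate_run(cfg, seed=1)
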