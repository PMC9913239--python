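import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermokin as tk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kpc():
    """Published KPC coefficients: (ArrheniusParams, DelayParams)."""
    return tk.cell_line_params("KPC")


@pytest.fixture(scope="session")
def kpc_arrhenius(kpc):
    return kpc[0]


@pytest.fixture(scope="session")
def kpc_delay(kpc):
    return kpc[1]


@pytest.fixture()
def noiseless_kpc_dataset(kpc):
    """Shoulder-bearing survival data on the standard design grid, no noise."""
    return tk.generate_viability_dataset({"KPC": kpc}, noise=tk.NOISELESS,
                                         recovery_scale={24.0: 1.0})


@pytest.fixture(scope="session")
def design_setpoints_k():
    return [c + 273.15 for c in (42.5, 44.0, 46.0, 50.0)]


def constant_profile_omega_oracle(params, temperature, duration):
    """Closed-form damage for isothermal exposure: Omega = k(T) * t."""
    return tk.rate_constant(params, temperature) * duration


@pytest.fixture(scope="session")
def omega_oracle():
    return constant_profile_omega_oracle
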