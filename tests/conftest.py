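import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spq

# deterministic hypothesis runs
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gold():
    return spq.GOLD


@pytest.fixture(scope="session")
def calibration():
    """A self-consistent (ionic calibration, transport efficiency) pair.

    Built so that the detector sensitivity is exactly 0.14 counts/ag at
    eta = 0.06, q = 0.346 mL/min, t_d = 100 us — the same settings the
    simulator fixtures use.
    """
    eta_true = 0.06
    s_true = 0.14
    f = s_true * eta_true * 0.346 * 1e-4 * (1e9 / 60.0)
    cal = spq.IonicCalibration(
        slope=f, intercept=0.0, r_squared=1.0, flow_rate=0.346, dwell_time=1e-4
    )
    eta = spq.TransportEfficiency(eta=eta_true)
    return cal, eta, s_true


@pytest.fixture(scope="session")
def monodisperse_60nm_trace():
    """30 s trace of 60 nm gold particles at 20/s over a low background."""
    spec = spq.SimulationSpec(
        background_mean=0.2,
        duration=30.0,
        particle_rate=20.0,
        size_distribution=spq.SizeDistribution("point", 60.0),
        counts_per_ag=0.14,
        seed=42,
    )
    trace, truth = spq.simulate_trace(spec)
    return spec, trace, truth
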