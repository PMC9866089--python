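"""Shared fixtures: reference calibration and reusable simulations.

Voltage-clamp simulations are the most expensive fixtures, so they are
session-scoped and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiocal.calibration import CalibrationParams
from cardiocal.synthetic_data import (
    CellParams,
    ProtocolSchedule,
    SimulationParams,
    StepProtocol,
    fura2_forward,
    simulate_concentration_trace,
    simulate_voltage_clamp,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib() -> CalibrationParams:
    return CalibrationParams(r_min=0.5, r_max=3.5, beta=1.0)


@pytest.fixture(scope="session")
def noiseless_caffeine_trace(calib):
    """Quiescent cell, caffeine at 2 s, k_eff 0.2 /s after SERCA nulling."""
    params = SimulationParams(beat_rate=0.0, leak_rate=0.0, duration=30.0, seed=1)
    conc = simulate_concentration_trace(
        params, ProtocolSchedule(events=[(2.0, "caffeine_on")])
    )
    return fura2_forward(conc, calib, noise_sd=0.0).calibrated(calib), params


@pytest.fixture(scope="session")
def passive_recording():
    """Wild-type-sized passive cell, 10 MOhm pipette, default protocol."""
    cell = CellParams(cm_true=51.9, rs=10.0, rin_true=435.1, g_na_max=0.0)
    return cell, simulate_voltage_clamp(cell)


@pytest.fixture(scope="session")
def short_protocol():
    """Single-step protocol: cheap sweeps for passive-only analyses."""
    return StepProtocol(v_start=-80.0, v_stop=-80.0, pulse_ms=100.0)
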