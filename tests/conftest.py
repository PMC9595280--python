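"""Shared fixtures: the expensive closed-loop runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from s3sim import ConditionConfig
from s3sim.protocol import reference_calibration, run_condition


@pytest.fixture(scope="session")
def reference():
    """Adapted reference circulation plus the frozen stiffness scale.

    Returns (kappa, adapted_params, steady_state, series, n_beats).
    """
    return reference_calibration()


@pytest.fixture(scope="session")
def reference_result():
    """Full reference pipeline result (also primes the internal cache)."""
    return run_condition(ConditionConfig.make("reference"), keep_series=True)


@pytest.fixture(scope="session")
def condition_results():
    """One pipeline result per protocol condition cell used by trend checks."""
    cells = [("aging", 1), ("aging", 3), ("aging", 6),
             ("MR", 1), ("MR", 2), ("MR", 3), ("MR", 4),
             ("TR", 1), ("TR", 4),
             ("MS", 1), ("MS", 4), ("TS", 1), ("TS", 4),
             ("ASD", 1), ("ASD", 4), ("VSD", 1), ("VSD", 4),
             ("HFpEF", 1), ("HFpEF", 3)]
    return {cell: run_condition(ConditionConfig.make(*cell)) for cell in cells}


def damped_sine(v_a: float, zeta: float, omega_n: float, t: np.ndarray) -> np.ndarray:
    """Closed-form underdamped free vibration with x(0)=0, x'(0)=v_a."""
    omega_d = omega_n * np.sqrt(1.0 - zeta**2)
    return v_a / omega_d * np.exp(-zeta * omega_n * t) * np.sin(omega_d * t)
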