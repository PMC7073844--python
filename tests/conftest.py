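"""Shared fixtures: default parameters and the three reference frying runs.

The three 9-minute simulations (constant 170 degC, and the two
temperature-step schedules switching at 3 and 4 min) are expensive, so they
run once per session at the default resolution and are shared by the
acceptance and invariant tests.
"""

from __future__ import annotations

import pytest

from frysim import (
    FryingSchedule,
    ModelParameters,
    NumericsConfig,
    simulate,
)

T_FRY_170C = 443.15
F_STEP = 0.95489
T_END = 540.0


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def numerics() -> NumericsConfig:
    return NumericsConfig(snapshot_times=(T_END,))


@pytest.fixture(scope="session")
def run_const170(params, numerics):
    """Constant 170 degC bath, 9 min, default parameters and resolution."""
    import time

    s = FryingSchedule(T_fry=T_FRY_170C, t_H=T_END, f=1.0, t_end=T_END)
    t0 = time.perf_counter()
    result = simulate(params, s, numerics)
    result.audit_totals["wall_seconds"] = time.perf_counter() - t0
    return result, s


@pytest.fixture(scope="session")
def run_tsfa3(params, numerics):
    """Temperature-step schedule: 170 degC for 3 min, then 150.0 degC."""
    s = FryingSchedule(T_fry=T_FRY_170C, t_H=180.0, f=F_STEP, t_end=T_END)
    return simulate(params, s, numerics), s


@pytest.fixture(scope="session")
def run_tsfa4(params, numerics):
    """Temperature-step schedule: 170 degC for 4 min, then 150.0 degC."""
    s = FryingSchedule(T_fry=T_FRY_170C, t_H=240.0, f=F_STEP, t_end=T_END)
    return simulate(params, s, numerics), s
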