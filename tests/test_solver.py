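"""Transport solver: gates, schedule, diffusion steps, and PDE invariants."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from frysim import (
    FieldState,
    FryingSchedule,
    Grid2D,
    ModelParameters,
    NumericsConfig,
    bath_temperature,
    evaporation_rate,
    gate_s_W,
    simulate,
)
from frysim.solver import step_heat, step_moisture
from frysim.verification import SlabBenchmark, slab_temperature

P = ModelParameters()


@pytest.mark.parametrize("T, expected", [
    (376.14, 0.0), (376.15, 1.0), (293.15, 0.0), (500.0, 1.0),
])
def test_evaporation_gate_threshold_inclusive(T, expected):
    assert gate_s_W(T, P) == expected


def test_evaporation_rate_values():
    assert evaporation_rate(1000.0, 370.0, P) == 0.0
    assert evaporation_rate(1000.0, 380.0, P) == pytest.approx(8.0)
    assert evaporation_rate(0.0, 400.0, P) == 0.0
    with pytest.raises(ValueError):
        evaporation_rate(-1.0, 400.0, P)


def test_bath_temperature_step_schedule():
    s = FryingSchedule(T_fry=443.15, t_H=180.0, f=0.95489, t_end=540.0)
    assert bath_temperature(0.0, s) == 443.15
    assert bath_temperature(179.99, s) == 443.15
    # the factor multiplies the absolute temperature: 170 degC -> 150.0 degC
    stepped = bath_temperature(180.0, s)
    assert stepped == pytest.approx(423.16, abs=0.01)
    assert stepped - 273.15 == pytest.approx(150.0, abs=0.01)
    const = FryingSchedule(T_fry=443.15, f=1.0)
    assert bath_temperature(1e4, const) == 443.15


def test_grid_geometry_half_width():
    g = Grid2D.from_params(P, NumericsConfig())
    assert g.x[0] == 0.0 and g.x[-1] == pytest.approx(P.W / 2)
    assert g.y[0] == 0.0 and g.y[-1] == pytest.approx(P.H)
    assert g.dx == pytest.approx(g.dy) == pytest.approx(0.125e-3)
    # control volumes tile the half-domain exactly
    assert g.cell_areas.sum() == pytest.approx(P.W / 2 * P.H, rel=1e-12)


def test_heat_step_equilibrium_and_maximum_principle():
    g = Grid2D.make(P.W, P.H, 9, 9)
    state = FieldState.initial(P, g)
    # bath at the strip temperature, no evaporation: nothing happens
    T_new, _ = step_heat(state, P.T_i, 1.0, g, P)
    np.testing.assert_allclose(T_new, P.T_i, rtol=1e-12)
    # hot bath: temperature rises but never exceeds the bath
    T_bath = 443.15
    for _ in range(50):
        state.T, _ = step_heat(state, T_bath, 1.0, g, P)
    assert state.T.max() < T_bath
    assert state.T.min() > P.T_i


def test_moisture_step_equilibrium_and_monotone_drying():
    g = Grid2D.make(P.W, P.H, 9, 9)
    state = FieldState.initial(P, g)
    state.C_w[:] = P.C_eq
    C_new, _ = step_moisture(state, 1.0, g, P)  # T=T_i, gate closed
    np.testing.assert_allclose(C_new, P.C_eq, rtol=1e-12)
    # above equilibrium, below the gate: every node loses water monotonically
    state.C_w[:] = P.C_wi
    prev = state.C_w.copy()
    for _ in range(20):
        state.C_w, _ = step_moisture(state, 1.0, g, P)
        assert np.all(state.C_w <= prev + 1e-12)
        assert np.all(state.C_w >= P.C_eq - 1e-9)
        prev = state.C_w.copy()


def test_heat_solver_matches_transient_slab_series_oracle():
    """1D constant-property limit vs the classical eigenfunction series.

    East face convective, y-faces insulated, no evaporation sink: the
    solver must match the series solution for a convectively heated slab
    (Biot = h L / k) to <0.5% of the overall temperature rise.
    """
    kappa, rho, cp = 0.5, 800.0, 3500.0
    T_bath = 390.0
    bench = SlabBenchmark(
        half_thickness=P.W / 2, conductivity=kappa, density=rho,
        heat_capacity=cp, h_t=P.h_t, T_i=P.T_i, T_bath=T_bath,
    )
    t_diff = bench.half_thickness**2 / bench.alpha  # one diffusion time
    g = Grid2D.make(P.W, P.H, 161, 3)
    state = FieldState.initial(P, g)
    dt = t_diff / 2000
    props = lambda T, C_w: (np.full_like(T, rho), np.full_like(T, cp),
                            np.full_like(T, kappa))
    no_sink = np.zeros_like(state.T)
    for _ in range(2000):
        state.T, _ = step_heat(state, T_bath, dt, g, P,
                               R_evp=no_sink, properties_fn=props,
                               faces=("east",))
    exact = slab_temperature(bench, g.x, t_diff)
    err = np.abs(state.T[1, :] - exact) / (T_bath - P.T_i)
    assert err.max() < 5e-3


def test_half_domain_matches_mirrored_full_width_run():
    """Symmetry: a full-width strip with convective x-faces, restricted to
    x >= midplane, reproduces the half-domain solution."""
    n_half = NumericsConfig(nx=10, ny=17, dt=0.1)
    s = FryingSchedule(T_fry=443.15, f=1.0, t_H=30.0, t_end=30.0)
    half = simulate(P, s, n_half)

    p_full = dataclasses.replace(P, W=2 * P.W)  # grid spans [0, W] after halving
    n_full = NumericsConfig(nx=19, ny=17, dt=0.1)
    full = simulate(p_full, s, n_full,
                    faces=("east", "west", "south", "north"))

    T_right = full.final_state.T[:, 9:]
    np.testing.assert_allclose(half.final_state.T, T_right, rtol=1e-10)
    np.testing.assert_allclose(half.final_state.C_w, full.final_state.C_w[:, 9:],
                               rtol=1e-9)


def test_simulation_is_deterministic():
    n = NumericsConfig(nx=8, ny=9, dt=0.2)
    s = FryingSchedule(T_fry=443.15, f=1.0, t_H=20.0, t_end=20.0)
    a = simulate(P, s, n)
    b = simulate(P, s, n)
    np.testing.assert_array_equal(a.final_state.T, b.final_state.T)
    np.testing.assert_array_equal(a.series.water_pct, b.series.water_pct)


def test_closed_system_conserves_water_and_temperature():
    """With insulated boundaries, a cold bath, and the gates shut, nothing
    enters or leaves: water and temperature stay put to roundoff."""
    p = dataclasses.replace(P, h_t=1e-30, k_m=1e-30)
    s = FryingSchedule(T_fry=P.T_i, f=1.0, t_H=30.0, t_end=30.0)
    res = simulate(p, s, NumericsConfig(nx=8, ny=9, dt=0.1))
    np.testing.assert_allclose(res.final_state.T, P.T_i, rtol=1e-12)
    np.testing.assert_allclose(res.final_state.C_w, P.C_wi, rtol=1e-12)


def test_initial_observables(run_const170, params):
    """t = 0: stated composition, cold strip, no acrylamide."""
    res, _ = run_const170
    first = res.series.to_dataframe().iloc[0]
    assert first.water_pct == pytest.approx(77.2, abs=0.2)
    assert first.aa_ugkg == 0.0
    assert first.T_surface_C == pytest.approx(20.0, abs=1e-9)
    assert first.T_core_C == pytest.approx(20.0, abs=1e-9)


def test_field_maximum_principles_on_reference_run(run_const170, params):
    res, s = run_const170
    state = res.final_state
    assert state.T.max() <= s.T_fry + 1e-2
    assert state.T.min() >= params.T_i - 1e-6
    assert state.C_w.min() >= 0.0
    assert state.C_w.max() <= params.C_wi * (1 + 1e-12)


def test_tsfa_never_exceeds_constant_frying_acrylamide(run_const170, run_tsfa3):
    """Lowering the bath temperature can only reduce acrylamide, at every
    recorded time."""
    const, _ = run_const170
    tsfa, _ = run_tsfa3
    np.testing.assert_array_equal(const.series.t, tsfa.series.t)
    assert np.all(tsfa.series.aa_avg <= const.series.aa_avg + 1e-9)
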