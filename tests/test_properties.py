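"""Component property polynomials, mixing rule, and Arrhenius diffusivity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frysim import (
    Composition,
    ModelParameters,
    component_conductivity,
    component_density,
    component_heat_capacity,
    effective_density,
    effective_diffusivity,
    mix_mass_fraction,
)

PAPER_COMP = Composition()


@pytest.mark.parametrize("fn, component, T_C, expected", [
    # constant terms at 0 degC
    (component_density, "water", 0.0, 997.18),
    (component_density, "carb", 0.0, 159.91),
    (component_density, "protein", 0.0, 1329.9),
    (component_heat_capacity, "water", 0.0, 4.1762),
    (component_heat_capacity, "protein", 0.0, 2.0082),
    (component_conductivity, "water", 0.0, 0.57109),
    (component_conductivity, "carb", 0.0, 0.2014),
    # direct polynomial evaluations away from 0 degC
    (component_density, "water", 20.0, 995.74),
    (component_heat_capacity, "water", 100.0, 4.1306),
    (component_conductivity, "water", 100.0, 0.68031),
])
def test_component_polynomials(fn, component, T_C, expected):
    assert fn(component, T_C) == pytest.approx(expected, abs=5e-3)


def test_corrected_set_differs_only_where_documented():
    # carbohydrate density mantissa is 10x the as-printed value
    assert component_density("carb", 0.0, "choi-okos-corrected") == pytest.approx(1599.1)
    assert component_density("carb", 0.0, "as-printed") == pytest.approx(159.91)
    # water heat capacity flips the sign pattern of its T terms
    as_p = component_heat_capacity("water", 100.0, "as-printed")
    corr = component_heat_capacity("water", 100.0, "choi-okos-corrected")
    assert as_p == pytest.approx(4.1306, abs=1e-3)
    assert corr == pytest.approx(4.2219, abs=1e-3)
    # conductivities identical between the sets
    assert component_conductivity("water", 80.0, "as-printed") == \
        component_conductivity("water", 80.0, "choi-okos-corrected")


def test_unknown_component_and_set_rejected():
    with pytest.raises(ValueError, match="component"):
        component_density("oil", 20.0)
    with pytest.raises(ValueError, match="coefficient set"):
        component_density("water", 20.0, "bogus")


def test_mixing_rule_is_unrenormalized_weighted_sum():
    # single component at weight 1
    one = Composition(omega_water=1.0, omega_carb=0.0, omega_protein=0.0)
    assert mix_mass_fraction({"water": 5.0, "carb": 99.0, "protein": 99.0}, one) == 5.0
    # the published composition at 20 degC: 0.987 total mass fraction kept as-is
    rho_e = effective_density(20.0, PAPER_COMP)
    assert rho_e == pytest.approx(833.2, abs=0.5)
    zero = Composition(omega_water=0.0, omega_carb=0.0, omega_protein=0.0)
    assert mix_mass_fraction({"water": 5.0, "carb": 7.0, "protein": 11.0}, zero) == 0.0


@given(
    a=st.floats(0, 2000), b=st.floats(0, 2000), scale=st.floats(0.1, 10),
)
@settings(max_examples=50, deadline=None)
def test_mixing_is_linear_in_each_component(a, b, scale):
    vals = {"water": a, "carb": b, "protein": 0.0}
    scaled = {"water": a * scale, "carb": b, "protein": 0.0}
    m0 = mix_mass_fraction({"water": 0.0, "carb": b, "protein": 0.0}, PAPER_COMP)
    m1 = mix_mass_fraction(vals, PAPER_COMP)
    m2 = mix_mass_fraction(scaled, PAPER_COMP)
    assert m2 - m0 == pytest.approx(scale * (m1 - m0), rel=1e-9, abs=1e-9)


def test_effective_density_ranges_distinguish_coefficient_sets():
    """A coefficient-set mix-up would be caught by disjoint density ranges."""
    T = np.linspace(20.0, 170.0, 16)
    as_printed = effective_density(T, PAPER_COMP, "as-printed")
    corrected = effective_density(T, PAPER_COMP, "choi-okos-corrected")
    assert np.all((as_printed > 700.0) & (as_printed < 900.0))
    assert np.all((corrected > 900.0) & (corrected < 1200.0))


def test_diffusivity_arrhenius_values_and_monotonicity():
    p = ModelParameters()
    assert effective_diffusivity(376.15, p) == pytest.approx(7.34e-10, rel=5e-3)
    # high-temperature limit approaches the pre-exponential
    assert effective_diffusivity(1e9, p) == pytest.approx(p.D0, rel=1e-4)
    T = np.linspace(300.0, 500.0, 100)
    D = effective_diffusivity(T, p)
    assert np.all(np.diff(D) > 0)
    with pytest.raises(ValueError):
        effective_diffusivity(-5.0, p)


def test_initial_water_fraction_anchor():
    """C_wi * M_W / rho_e(T_i) reproduces the stated 77.2% initial water."""
    p = ModelParameters()
    rho_e = effective_density(p.T_i - 273.15, p.composition)
    assert 100.0 * p.C_wi * p.M_W / rho_e == pytest.approx(77.2, abs=0.2)
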