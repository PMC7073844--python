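"""Temperature-dependent thermophysical properties of the potato strip.

Each component (water, carbohydrate, protein) carries a quadratic
polynomial in temperature (deg C) for density (kg/m^3), specific heat
(kJ/(kg K)) and thermal conductivity (W/(m K)), in the style of the
Choi–Okos food-property correlations.  Strip-level "effective" properties
are mass-fraction-weighted arithmetic sums of the component values; the sum
is intentionally NOT renormalized by the total mass fraction (0.987 for the
default composition).

Two coefficient sets are selectable:

* ``"as-printed"`` (default) — the correlation set of the source model,
  taken verbatim.  Its carbohydrate density constant (159.91 kg/m^3) is an
  order of magnitude below the usual Choi–Okos value, which makes the
  effective density ~833 kg/m^3 at 20 deg C; this set is kept as the default
  because it is internally consistent with the model's initial water
  concentration (C_wi * M_W / rho_e = 77.3%, matching the stated 77.2%
  wet-basis water content).
* ``"choi-okos-corrected"`` — identical except the carbohydrate density
  mantissa is restored to 1.5991e3 and the water heat-capacity polynomial
  uses the standard Choi–Okos sign pattern.  Provided for sensitivity
  analysis.

Water diffusivity is Arrhenius in absolute temperature:
``D_e(T) = D0 * exp(-Ea_dif / (R_g T))``.
"""

from __future__ import annotations

import numpy as np

from .params import Composition, ModelParameters

__all__ = [
    "COMPONENTS",
    "COEFFICIENT_SETS",
    "component_density",
    "component_heat_capacity",
    "component_conductivity",
    "mix_mass_fraction",
    "effective_density",
    "effective_heat_capacity",
    "effective_conductivity",
    "effective_diffusivity",
]

COMPONENTS = ("water", "carb", "protein")

# (a0, a1, a2) -> a0 + a1*T + a2*T^2, T in deg C
_AS_PRINTED = {
    "density": {  # kg/m^3
        "carb": (1.5991e2, -0.31046, 0.0),
        "protein": (13.299e2, -0.51814, 0.0),
        "water": (9.9718e2, 3.1439e-3, -3.7574e-3),
    },
    "heat_capacity": {  # kJ/(kg K)
        "carb": (1.5488, 1.9625e-3, -5.9399e-6),
        "protein": (2.0082, 1.2089e-3, -1.3129e-6),
        "water": (4.1762, 9.0862e-5, -5.4731e-6),
    },
    "conductivity": {  # W/(m K)
        "carb": (2.014e-1, 1.3874e-3, -4.3312e-6),
        "protein": (1.788e-1, -1.1958e-3, -2.7178e-6),
        "water": (5.7109e-1, 1.7625e-3, -6.7036e-6),
    },
}

_CORRECTED = {
    "density": {
        **_AS_PRINTED["density"],
        "carb": (1.5991e3, -0.31046, 0.0),
    },
    "heat_capacity": {
        **_AS_PRINTED["heat_capacity"],
        "water": (4.1762, -9.0862e-5, 5.4731e-6),
    },
    "conductivity": dict(_AS_PRINTED["conductivity"]),
}

COEFFICIENT_SETS = {
    "as-printed": _AS_PRINTED,
    "choi-okos-corrected": _CORRECTED,
}

#: Documented validity window of the polynomials, deg C.
T_VALID_C = (-20.0, 250.0)


def _poly(coeffs: tuple[float, float, float], T_C):
    a0, a1, a2 = coeffs
    T_C = np.asarray(T_C, dtype=float)
    out = a0 + a1 * T_C + a2 * T_C * T_C
    return out if out.ndim else float(out)


def _component_property(kind: str, component: str, T_C, coefficient_set: str):
    try:
        table = COEFFICIENT_SETS[coefficient_set]
    except KeyError:
        raise ValueError(
            f"unknown coefficient set {coefficient_set!r}; "
            f"expected one of {sorted(COEFFICIENT_SETS)}"
        ) from None
    try:
        coeffs = table[kind][component]
    except KeyError:
        raise ValueError(
            f"unknown component {component!r}; expected one of {COMPONENTS}"
        ) from None
    return _poly(coeffs, T_C)


def component_density(component: str, T_C, coefficient_set: str = "as-printed"):
    """Density of one strip component, kg/m^3, at temperature ``T_C`` (deg C)."""
    return _component_property("density", component, T_C, coefficient_set)


def component_heat_capacity(component: str, T_C, coefficient_set: str = "as-printed"):
    """Specific heat of one component, kJ/(kg K), at ``T_C`` (deg C).

    Note the kJ unit: the transport solver multiplies by 1e3 where SI J is
    needed.
    """
    return _component_property("heat_capacity", component, T_C, coefficient_set)


def component_conductivity(component: str, T_C, coefficient_set: str = "as-printed"):
    """Thermal conductivity of one component, W/(m K), at ``T_C`` (deg C)."""
    return _component_property("conductivity", component, T_C, coefficient_set)


def mix_mass_fraction(values: dict[str, float], omegas: Composition):
    """Mass-fraction-weighted arithmetic sum over components.

    ``sum_j value_j * omega_j``, exactly — no renormalization by the total
    mass fraction.  ``values`` maps component name -> property value (scalars
    or broadcastable arrays).
    """
    w = omegas.as_dict()
    total = 0.0
    for component, value in values.items():
        if component not in w:
            raise ValueError(f"unknown component {component!r}")
        total = total + np.asarray(value, dtype=float) * w[component]
    out = np.asarray(total, dtype=float)
    return out if out.ndim else float(out)


def _effective(kind: str, T_C, omegas: Composition, coefficient_set: str):
    values = {
        c: _component_property(kind, c, T_C, coefficient_set) for c in COMPONENTS
    }
    return mix_mass_fraction(values, omegas)


def effective_density(T_C, omegas: Composition, coefficient_set: str = "as-printed"):
    """Effective strip density rho_e, kg/m^3, at ``T_C`` (deg C)."""
    return _effective("density", T_C, omegas, coefficient_set)


def effective_heat_capacity(T_C, omegas: Composition, coefficient_set: str = "as-printed"):
    """Effective strip specific heat C_p,e, kJ/(kg K), at ``T_C`` (deg C)."""
    return _effective("heat_capacity", T_C, omegas, coefficient_set)


def effective_conductivity(T_C, omegas: Composition, coefficient_set: str = "as-printed"):
    """Effective strip thermal conductivity kappa_e, W/(m K), at ``T_C``."""
    return _effective("conductivity", T_C, omegas, coefficient_set)


def effective_diffusivity(T_K, p: ModelParameters):
    """Arrhenius effective water diffusivity, m^2/s, at ``T_K`` (kelvin)."""
    T_K = np.asarray(T_K, dtype=float)
    if np.any(T_K <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = p.D0 * np.exp(-p.Ea_dif / (p.R_g * T_K))
    return out if out.ndim else float(out)
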