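"""Model parameters, strip composition, frying schedule, and numerics config.

Everything the simulator needs is collected in four small immutable objects:

* :class:`Composition` — wet-basis mass fractions of water / carbohydrate /
  protein in the raw strip.
* :class:`ModelParameters` — physical and kinetic constants (concentrations,
  transfer coefficients, activation energies, gate temperatures).
* :class:`FryingSchedule` — the oil-bath temperature program, including the
  temperature-step schedule (bath drops by a factor ``f`` on the absolute
  temperature at time ``t_H``).
* :class:`NumericsConfig` — grid resolution, time step, output control.

A single YAML config file (``schema: 1``) can override any field; unspecified
fields take the documented defaults.  Activation energies are stored in J/mol
internally; the config may give them in kJ/mol via an ``energy_units`` key,
matching the units tables in the food-engineering literature usually print.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "Composition",
    "ModelParameters",
    "FryingSchedule",
    "NumericsConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "save_config",
    "dump_config",
    "validate_parameters",
    "validate_schedule",
    "validate_numerics",
    "default_config_path",
]

SCHEMA_VERSION = 1

#: Water evaporation gate: vaporization is switched on at/above 103 deg C.
T_EVAP_DEFAULT = 376.15
#: Acrylamide gate: Maillard kinetics are switched on at/above 120 deg C.
T_AA_DEFAULT = 393.15


class ConfigError(ValueError):
    """Raised for unparseable, unknown, or invalid configuration input."""


@dataclass(frozen=True)
class Composition:
    """Wet-basis mass fractions of the raw potato strip.

    The default composition (77.2% water, 18.8% carbohydrate, 2.7% protein)
    sums to 0.987; the remainder (ash, fat, fibre) carries no dedicated
    property correlation and is deliberately NOT renormalized away.
    """

    omega_water: float = 0.772
    omega_carb: float = 0.188
    omega_protein: float = 0.027

    @property
    def total(self) -> float:
        return self.omega_water + self.omega_carb + self.omega_protein

    def as_dict(self) -> dict[str, float]:
        return {
            "water": self.omega_water,
            "carb": self.omega_carb,
            "protein": self.omega_protein,
        }


@dataclass(frozen=True)
class ModelParameters:
    """Physical, transport, and kinetic constants of the frying model.

    Units are SI throughout (concentrations mol/m^3, energies J/mol,
    temperatures K).  Defaults are the published input-parameter set for an
    8.5 x 8.5 mm potato strip fried in oil.
    """

    C_Ai: float = 6.8          # initial reducing sugar, mol/m^3
    C_eq: float = 9265.0       # equilibrium surface water conc., mol/m^3
    C_wi: float = 35778.0      # initial water concentration, mol/m^3
    D0: float = 5.0e-6         # water diffusivity pre-exponential, m^2/s
    Ea_AA: float = 44.5e3      # activation energy, acrylamide formation, J/mol
    Ea_D: float = 21.3e3       # activation energy, acrylamide degradation, J/mol
    Ea_dif: float = 27.6e3     # activation energy, water diffusivity, J/mol
    H: float = 8.5e-3          # strip height, m
    W: float = 8.5e-3          # strip width, m
    H_evp: float = 2.3e6       # latent heat of vaporization, J/kg
    h_t: float = 105.0         # convective heat-transfer coeff., W/(m^2 K)
    k_evp: float = 8.0e-3      # evaporation rate constant, 1/s
    k0: float = 22.0           # kinetic pre-exponential factor, 1/s
    k_m: float = 5.2e-4        # convective mass-transfer coeff., m/s
    M_A: float = 0.172         # kinetic mass-conversion constant, kg/mol
    M_W: float = 0.018015      # molar mass of water, kg/mol
    R_g: float = 8.314         # universal gas constant, J/(mol K)
    T_i: float = 293.15        # initial strip temperature, K
    T_evap: float = T_EVAP_DEFAULT  # evaporation gate threshold, K
    T_AA: float = T_AA_DEFAULT      # acrylamide gate threshold, K
    composition: Composition = field(default_factory=Composition)


@dataclass(frozen=True)
class FryingSchedule:
    """Oil-bath temperature program.

    The bath holds ``T_fry`` (K) until ``t_H`` (s) and then drops to
    ``f * T_fry`` — the step factor multiplies the ABSOLUTE temperature, so
    f = 0.95489 turns a 170 deg C bath into a 150.0 deg C one.  With f = 1
    the schedule reduces to constant-temperature frying.
    """

    T_fry: float = 443.15   # bath temperature before the step, K
    t_H: float = 540.0      # step time, s
    f: float = 1.0          # step factor on absolute temperature
    t_end: float = 540.0    # total frying time, s


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and output settings (solver plumbing, not physics).

    The default grid (nx=35, ny=69) puts nodes every 0.125 mm on the
    half-width domain [0, W/2] x [0, H]; dt = 0.05 s resolves the sharp
    evaporation gate without making the (unconditionally stable) implicit
    diffusion steps expensive.
    """

    nx: int = 35
    ny: int = 69
    dt: float = 0.05
    snapshot_times: tuple[float, ...] = ()
    scheme: str = "backward-euler-split"
    property_coefficient_set: str = "as-printed"
    gate_smoothing_K: float = 0.0   # 0 = sharp Heaviside gates
    update_composition: bool = True  # re-derive local omega_w from local C_w
    output_every: float = 1.0       # observable recording interval, s


# --------------------------------------------------------------------------
# validation

def _positive_fields() -> tuple[str, ...]:
    return (
        "C_Ai", "C_eq", "C_wi", "D0", "Ea_AA", "Ea_D", "Ea_dif", "H", "W",
        "H_evp", "h_t", "k_evp", "k0", "k_m", "M_A", "M_W", "R_g", "T_i",
        "T_evap", "T_AA",
    )


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every invariant of a parameter set; return violation messages.

    Reports rather than raises so a config loader can collect all problems
    at once.  An empty list means the parameters are valid.
    """
    problems: list[str] = []
    for name in _positive_fields():
        value = getattr(p, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            problems.append(f"{name}: must be a finite number, got {value!r}")
        elif value <= 0:
            problems.append(f"{name}: must be strictly positive, got {value}")
    # activation energies are stored in J/mol; a value of order 10-100 almost
    # certainly means kJ/mol slipped in unconverted
    for name in ("Ea_AA", "Ea_D", "Ea_dif"):
        value = getattr(p, name)
        if 0 < value < 1000.0:
            problems.append(
                f"{name}: {value} J/mol is ~1000x below the plausible range; "
                "was a kJ/mol value stored without conversion?"
            )
    c = p.composition
    for name, value in (
        ("omega_water", c.omega_water),
        ("omega_carb", c.omega_carb),
        ("omega_protein", c.omega_protein),
    ):
        if not (0.0 <= value <= 1.0):
            problems.append(f"composition.{name}: must lie in [0, 1], got {value}")
    if not (0.95 < c.total <= 1.0 + 1e-12):
        problems.append(
            f"composition: mass fractions sum to {c.total:.4f}, "
            "expected a sum in (0.95, 1.0]"
        )
    return problems


def validate_schedule(s: FryingSchedule) -> list[str]:
    problems: list[str] = []
    if not s.T_fry > 0:
        problems.append(f"schedule.T_fry: must be positive (K), got {s.T_fry}")
    if not 0 < s.f <= 1.0:
        problems.append(f"schedule.f: must lie in (0, 1], got {s.f}")
    if not s.t_end > 0:
        problems.append(f"schedule.t_end: must be positive, got {s.t_end}")
    if not 0 < s.t_H:
        problems.append(f"schedule.t_H: must be positive, got {s.t_H}")
    elif s.t_end > 0 and s.t_H > s.t_end and s.f != 1.0:
        problems.append(
            f"schedule.t_H: step time {s.t_H} s exceeds total time {s.t_end} s"
        )
    return problems


def validate_numerics(n: NumericsConfig) -> list[str]:
    problems: list[str] = []
    if n.nx < 3 or n.ny < 3:
        problems.append(f"numerics: nx and ny must be >= 3, got nx={n.nx}, ny={n.ny}")
    if not n.dt > 0:
        problems.append(f"numerics.dt: must be positive, got {n.dt}")
    if n.property_coefficient_set not in ("as-printed", "choi-okos-corrected"):
        problems.append(
            "numerics.property_coefficient_set: must be 'as-printed' or "
            f"'choi-okos-corrected', got {n.property_coefficient_set!r}"
        )
    if n.gate_smoothing_K < 0:
        problems.append(
            f"numerics.gate_smoothing_K: must be >= 0, got {n.gate_smoothing_K}"
        )
    if n.output_every <= 0:
        problems.append(f"numerics.output_every: must be positive, got {n.output_every}")
    if any(t < 0 for t in n.snapshot_times):
        problems.append("numerics.snapshot_times: times must be >= 0")
    return problems


# --------------------------------------------------------------------------
# config I/O

_ENERGY_FIELDS = ("Ea_AA", "Ea_D", "Ea_dif")
_TOP_KEYS = {"schema", "parameters", "composition", "schedule", "numerics", "meta"}
_COMPOSITION_KEYS = {"water", "carb", "protein"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)} - {"composition"}
_PARAM_KEYS |= {"energy_units"}
_SCHEDULE_KEYS = {f.name for f in dataclasses.fields(FryingSchedule)}
_NUMERICS_KEYS = {f.name for f in dataclasses.fields(NumericsConfig)}


def _check_keys(section: str, given: dict[str, Any], allowed: set[str]) -> None:
    for key in given:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")


def loads_config(
    text: str,
) -> tuple[ModelParameters, FryingSchedule, NumericsConfig]:
    """Parse a YAML config string into validated objects.

    Unknown keys are rejected (naming the key) rather than ignored, so a
    typo cannot silently fall back to a default.
    """
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("<root>", raw, _TOP_KEYS)
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config schema {schema!r} (expected {SCHEMA_VERSION})")

    par = dict(raw.get("parameters") or {})
    _check_keys("parameters", par, _PARAM_KEYS)
    energy_units = par.pop("energy_units", "J/mol")
    if energy_units not in ("J/mol", "kJ/mol"):
        raise ConfigError(
            f"parameters.energy_units: expected 'J/mol' or 'kJ/mol', got {energy_units!r}"
        )
    if energy_units == "kJ/mol":
        for name in _ENERGY_FIELDS:
            if name in par:
                par[name] = float(par[name]) * 1e3

    comp_raw = dict(raw.get("composition") or {})
    _check_keys("composition", comp_raw, _COMPOSITION_KEYS)
    comp_kwargs = {}
    if "water" in comp_raw:
        comp_kwargs["omega_water"] = float(comp_raw["water"])
    if "carb" in comp_raw:
        comp_kwargs["omega_carb"] = float(comp_raw["carb"])
    if "protein" in comp_raw:
        comp_kwargs["omega_protein"] = float(comp_raw["protein"])
    composition = Composition(**comp_kwargs)

    params = ModelParameters(
        composition=composition,
        **{k: float(v) for k, v in par.items()},
    )

    sched_raw = dict(raw.get("schedule") or {})
    _check_keys("schedule", sched_raw, _SCHEDULE_KEYS)
    sched_kwargs = {k: float(v) for k, v in sched_raw.items()}
    # a schedule that gives t_end but no step time defaults to "no step"
    if "t_H" not in sched_kwargs and "t_end" in sched_kwargs:
        sched_kwargs["t_H"] = sched_kwargs["t_end"]
    schedule = FryingSchedule(**sched_kwargs)

    num_raw = dict(raw.get("numerics") or {})
    _check_keys("numerics", num_raw, _NUMERICS_KEYS)
    if "snapshot_times" in num_raw:
        num_raw["snapshot_times"] = tuple(float(t) for t in num_raw["snapshot_times"])
    numerics = NumericsConfig(**num_raw)

    problems = (
        validate_parameters(params)
        + validate_schedule(schedule)
        + validate_numerics(numerics)
    )
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return params, schedule, numerics


def load_config(
    path: str | Path,
) -> tuple[ModelParameters, FryingSchedule, NumericsConfig]:
    """Load and validate a YAML config file.  See :func:`loads_config`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    return loads_config(path.read_text())


def dump_config(
    p: ModelParameters,
    s: FryingSchedule,
    n: NumericsConfig,
    meta: dict[str, Any] | None = None,
) -> str:
    """Serialize a full configuration (every field explicit) to YAML.

    The output is itself a valid config: ``loads_config(dump_config(...))``
    round-trips every field bit-exactly.  Energies are written in J/mol.
    """
    doc: dict[str, Any] = {"schema": SCHEMA_VERSION}
    if meta:
        doc["meta"] = dict(meta)
    par = {k: getattr(p, k) for k in sorted(_PARAM_KEYS - {"energy_units"})}
    par["energy_units"] = "J/mol"
    doc["parameters"] = par
    doc["composition"] = {
        "water": p.composition.omega_water,
        "carb": p.composition.omega_carb,
        "protein": p.composition.omega_protein,
    }
    doc["schedule"] = {k: getattr(s, k) for k in sorted(_SCHEDULE_KEYS)}
    num = {k: getattr(n, k) for k in sorted(_NUMERICS_KEYS)}
    num["snapshot_times"] = list(n.snapshot_times)
    doc["numerics"] = num
    return yaml.safe_dump(doc, sort_keys=False)


def save_config(
    path: str | Path,
    p: ModelParameters,
    s: FryingSchedule,
    n: NumericsConfig,
    meta: dict[str, Any] | None = None,
) -> None:
    Path(path).write_text(dump_config(p, s, n, meta=meta))


def default_config_path(name: str) -> Path:
    """Path of a packaged default config (e.g. ``paper_170C``)."""
    here = Path(__file__).parent / "configs"
    candidate = here / f"{name}.yaml" if not name.endswith(".yaml") else here / name
    if not candidate.exists():
        available = ", ".join(sorted(q.stem for q in here.glob("*.yaml")))
        raise ConfigError(f"no packaged config {name!r}; available: {available}")
    return candidate
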