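"""Reported quantities: water content, acrylamide in µg/kg, temperature probes.

The raw solver state carries molar concentrations (mol/m^3) and kelvin
temperatures on the half-width grid; everything the frying literature
actually reports is derived here:

* **average water content** — wet-basis percent, computed as the ratio of
  the area-weighted mean water mass density to the area-weighted mean
  effective strip density (ratio of means, not mean of ratios — this is the
  convention that reproduces the 77.2% initial water anchor exactly),
* **acrylamide** — µg per kg of strip, via the mass-conversion constant
  ``M_A`` (kg/mol) and the local effective density,
* **temperature probes** — "surface" is the lateral-face midpoint
  (x = W/2, y = H/2), "core" is the strip centre (x = 0 on the symmetry
  plane, y = H/2).  The surface probe is deliberately NOT the corner: the
  corner is the hottest node of the field and runs above the reported
  surface trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import properties
from .kinetics import KineticState
from .params import ModelParameters

__all__ = [
    "TimeSeries",
    "Snapshot",
    "average_water_percent",
    "nodal_water_percent",
    "acrylamide_ugkg",
    "probe_temperatures",
    "probe_indices",
    "field_range",
]


@dataclass
class TimeSeries:
    """Observable trajectories of one simulation run (one row per record)."""

    t: np.ndarray                   # s
    water_pct: np.ndarray           # % wet basis
    aa_avg: np.ndarray              # µg/kg
    T_surface_C: np.ndarray         # deg C
    T_core_C: np.ndarray            # deg C
    T_avg_C: np.ndarray             # area-weighted mean, deg C
    mass_residual: np.ndarray       # relative discrete water-balance residual
    energy_residual: np.ndarray     # relative discrete energy-balance residual

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "water_pct": self.water_pct,
                "aa_ugkg": self.aa_avg,
                "T_surface_C": self.T_surface_C,
                "T_core_C": self.T_core_C,
                "T_avg_C": self.T_avg_C,
                "mass_residual": self.mass_residual,
                "energy_residual": self.energy_residual,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def at_time(self, t: float) -> dict[str, float]:
        """Row nearest to time ``t`` (s), as a plain dict."""
        i = int(np.argmin(np.abs(self.t - t)))
        df = self.to_dataframe()
        return {k: float(v) for k, v in df.iloc[i].items()}


@dataclass
class Snapshot:
    """Full nodal fields at one instant, for 2D distribution plots."""

    t: float
    x: np.ndarray                  # m, (nx,)
    y: np.ndarray                  # m, (ny,)
    T: np.ndarray                  # K, (ny, nx)
    C_w: np.ndarray                # mol/m^3, (ny, nx)
    kinetics: KineticState = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x_m": X.ravel(),
                "y_m": Y.ravel(),
                "T_K": self.T.ravel(),
                "C_w_mol_m3": self.C_w.ravel(),
                "C_A_mol_m3": self.kinetics.C_A.ravel(),
                "C_AA_mol_m3": self.kinetics.C_AA.ravel(),
                "C_D_mol_m3": self.kinetics.C_D.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cell_weights(nx: int, ny: int, dx: float, dy: float) -> np.ndarray:
    """Control-volume areas of the node-centred grid (half cells at edges)."""
    wx = np.full(nx, dx)
    wx[0] = wx[-1] = dx / 2.0
    wy = np.full(ny, dy)
    wy[0] = wy[-1] = dy / 2.0
    return np.outer(wy, wx)


def _weights_like(T: np.ndarray, grid) -> np.ndarray:
    if grid is not None:
        return grid.cell_areas
    ny, nx = T.shape
    return _cell_weights(nx, ny, 1.0, 1.0)


def average_water_percent(state, p: ModelParameters, grid=None,
                          coefficient_set: str = "as-printed") -> float:
    """Domain-average wet-basis water content, percent.

    ``100 * <C_w> * M_W / <rho_e(T)>`` with area-weighted means over the
    half-domain; the effective density uses the fixed initial composition at
    the local temperature.
    """
    w = _weights_like(state.T, grid)
    rho_e = properties.effective_density(
        state.T - 273.15, p.composition, coefficient_set
    )
    mean_cw = float(np.sum(state.C_w * w) / np.sum(w))
    mean_rho = float(np.sum(rho_e * w) / np.sum(w))
    return 100.0 * mean_cw * p.M_W / mean_rho


def nodal_water_percent(state, p: ModelParameters,
                        coefficient_set: str = "as-printed") -> np.ndarray:
    """Nodewise wet-basis water content, percent (for 2D distributions)."""
    rho_e = properties.effective_density(
        state.T - 273.15, p.composition, coefficient_set
    )
    return 100.0 * state.C_w * p.M_W / rho_e


def acrylamide_ugkg(C_AA, state, p: ModelParameters, grid=None,
                    coefficient_set: str = "as-printed"):
    """Convert acrylamide concentration to µg per kg of strip.

    ``1e9 * C_AA * M_A / rho_e``.  If ``C_AA`` is a nodal array matching the
    state, the conversion is applied nodewise with the local density; if it
    is a scalar (e.g. an area-weighted mean), the area-weighted mean density
    is used.
    """
    C_AA = np.asarray(C_AA, dtype=float)
    if np.any(C_AA < 0):
        raise ValueError("acrylamide concentration must be >= 0")
    rho_e = properties.effective_density(
        state.T - 273.15, p.composition, coefficient_set
    )
    if C_AA.ndim == 0:
        w = _weights_like(state.T, grid)
        mean_rho = float(np.sum(rho_e * w) / np.sum(w))
        return 1e9 * float(C_AA) * p.M_A / mean_rho
    return 1e9 * C_AA * p.M_A / rho_e


def average_acrylamide_ugkg(state, p: ModelParameters, grid=None,
                            coefficient_set: str = "as-printed") -> float:
    """Area-weighted mean acrylamide content of the strip, µg/kg."""
    w = _weights_like(state.T, grid)
    mean_caa = float(np.sum(state.kinetics.C_AA * w) / np.sum(w))
    return acrylamide_ugkg(mean_caa, state, p, grid, coefficient_set)


def probe_indices(nx: int, ny: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(surface, core) probe node indices as (j, i) pairs.

    Surface: lateral-face midpoint (x = W/2, y = H/2).  Core: strip centre
    (x = 0 symmetry plane, y = H/2).  With odd ``ny`` the midpoint is exact.
    """
    j_mid = (ny - 1) // 2
    return (j_mid, nx - 1), (j_mid, 0)


def probe_temperatures(state, grid=None) -> tuple[float, float]:
    """(T_surface, T_core) in deg C at the standard probe nodes."""
    ny, nx = state.T.shape
    (js, i_s), (jc, ic) = probe_indices(nx, ny)
    return float(state.T[js, i_s] - 273.15), float(state.T[jc, ic] - 273.15)


def field_range(snapshot: Snapshot, which: str, p: ModelParameters,
                coefficient_set: str = "as-printed") -> tuple[float, float]:
    """Nodal (min, max) of a snapshot field in reporting units.

    ``which`` is one of ``"T"`` (deg C), ``"C_w"`` (% wet basis, nodewise),
    ``"AA"`` (µg/kg, nodewise).
    """
    if which == "T":
        values = snapshot.T - 273.15
    elif which == "C_w":
        values = nodal_water_percent(snapshot, p, coefficient_set)
    elif which == "AA":
        values = acrylamide_ugkg(snapshot.kinetics.C_AA, snapshot, p,
                                 coefficient_set=coefficient_set)
    else:
        raise ValueError(f"unknown field {which!r}; expected 'T', 'C_w' or 'AA'")
    return float(np.min(values)), float(np.max(values))
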