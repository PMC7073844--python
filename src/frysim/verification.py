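"""Independent analytic references and conservation audits for the test suite.

The transient-slab benchmark is the classical eigenfunction series for
one-dimensional conduction in a slab of half-thickness L, initially at T_i,
convectively heated on the exposed face (Biot number Bi = h L / k), with a
symmetry plane at x = 0:

    theta(x, t) = sum_n A_n cos(lambda_n x / L) exp(-lambda_n^2 Fo)

with eigenvalues lambda_n solving lambda tan(lambda) = Bi,
A_n = 2 sin(lambda_n) / (lambda_n + sin(lambda_n) cos(lambda_n)), and
Fo = alpha t / L^2.  It is evaluated completely independently of the PDE
solver and serves as its oracle in the constant-property, no-sink 1D limit.

``run_audits`` checks the discrete conservation counters a simulation
accumulates (water mass, energy) together with the maximum principles and
water monotonicity; it reports violations rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["SlabBenchmark", "slab_temperature", "slab_eigenvalues", "run_audits"]


@dataclass(frozen=True)
class SlabBenchmark:
    """Constant-property convectively heated slab, symmetric about x = 0."""

    half_thickness: float       # L, m
    conductivity: float         # k, W/(m K)
    density: float              # rho, kg/m^3
    heat_capacity: float        # c_p, J/(kg K)
    h_t: float                  # convective coefficient, W/(m^2 K)
    T_i: float                  # initial temperature, K
    T_bath: float               # ambient temperature, K
    n_terms: int = 100

    @property
    def biot(self) -> float:
        return self.h_t * self.half_thickness / self.conductivity

    @property
    def alpha(self) -> float:
        return self.conductivity / (self.density * self.heat_capacity)


def slab_eigenvalues(biot: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` positive roots of  lambda * tan(lambda) = Bi.

    Root n lives in (n*pi, n*pi + pi/2); each is bracketed there and found
    by scalar root finding.
    """
    if biot <= 0 or not np.isfinite(biot):
        raise ValueError("Biot number must be positive and finite")
    eps = 1e-12
    roots = []
    for n in range(n_terms):
        lo = n * np.pi + eps
        hi = n * np.pi + np.pi / 2 - eps

        def f(lam):
            return lam * np.tan(lam) - biot

        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))
    return np.asarray(roots)


def slab_temperature(b: SlabBenchmark, x, t: float):
    """Series solution T(x, t) in K; ``x`` measured from the midplane."""
    if t < 0:
        raise ValueError("t must be >= 0")
    x = np.asarray(x, dtype=float)
    if t == 0.0:
        out = np.full_like(x, b.T_i)
        return out if out.ndim else float(out)
    lam = slab_eigenvalues(b.biot, b.n_terms)
    A = 2.0 * np.sin(lam) / (lam + np.sin(lam) * np.cos(lam))
    Fo = b.alpha * t / b.half_thickness**2
    xi = x / b.half_thickness
    theta = np.sum(
        A[:, None] * np.cos(np.outer(lam, xi)) * np.exp(-(lam**2) * Fo)[:, None],
        axis=0,
    ).reshape(x.shape)
    out = b.T_bath + (b.T_i - b.T_bath) * theta
    return out if out.ndim else float(out)


def run_audits(result, p, s, rtol_mass: float = 1e-3,
               rtol_energy: float = 1e-2) -> list[str]:
    """Check conservation and qualitative invariants of a finished run.

    ``result`` is a :class:`frysim.solver.SimulationResult`.  Returns a list
    of violation descriptions (empty = all audits pass):

    * cumulative water balance closes within ``rtol_mass`` of initial water,
    * cumulative energy balance closes within ``rtol_energy`` of boundary
      heat input,
    * maximum principles: T within [T_i, max bath temperature], C_w within
      [0, C_wi] (small tolerance for roundoff),
    * average water content never increases.
    """
    problems: list[str] = []
    series = result.series

    mass_res = float(np.max(np.abs(series.mass_residual)))
    if mass_res > rtol_mass:
        problems.append(
            f"water-mass balance residual {mass_res:.3e} exceeds {rtol_mass:.1e}"
        )
    energy_res = float(np.max(np.abs(series.energy_residual)))
    if energy_res > rtol_energy:
        problems.append(
            f"energy balance residual {energy_res:.3e} exceeds {rtol_energy:.1e}"
        )

    state = result.final_state
    T_max_allowed = s.T_fry + 1e-2
    if float(state.T.max()) > T_max_allowed:
        problems.append(
            f"temperature maximum principle violated: T_max={state.T.max():.3f} K "
            f"> bath {s.T_fry:.2f} K"
        )
    if float(state.T.min()) < p.T_i - 1e-6:
        problems.append(
            f"temperature fell below the initial value: T_min={state.T.min():.3f} K"
        )
    if float(state.C_w.min()) < -1e-9:
        problems.append(f"negative water concentration: {state.C_w.min():.3e}")
    if float(state.C_w.max()) > p.C_wi * (1 + 1e-9):
        problems.append(
            f"water concentration exceeds the initial value: {state.C_w.max():.3f}"
        )

    # the wet-basis percent divides by the mean effective density, which
    # falls as the strip heats, so the percent may tick up slightly during
    # early heating even though the water inventory strictly decreases;
    # anything beyond that slack indicates a genuine water source
    dw = np.diff(series.water_pct)
    if dw.size and float(dw.max()) > 0.05:
        problems.append(
            f"average water content increased by {dw.max():.3f} points between records"
        )
    if float(series.aa_avg.min()) < 0:
        problems.append("negative average acrylamide")
    return problems
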