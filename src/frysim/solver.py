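"""Coupled heat/moisture transport with evaporation sink and per-node kinetics.

The strip cross-section is modelled on the half-width domain
[0, W/2] x [0, H]: x = 0 is the symmetry plane (zero flux) and the other
three faces exchange heat and water with the oil bath through Robin
(convective) boundary conditions.  Per time step the simulator applies, in
order:

1. the bath temperature from the frying schedule (a step program: T_fry
   until t_H, then f * T_fry on the absolute scale),
2. one backward-Euler heat-diffusion step with temperature-dependent
   effective properties frozen at step start and an explicit evaporative
   heat sink ``R_evp * H_evp * M_W``,
3. one backward-Euler moisture-diffusion step with Arrhenius diffusivity
   frozen at the current temperature and the same evaporation sink,
4. the exact constant-temperature kinetics update at each node's new
   temperature.

Evaporation is gated: water vaporizes only where the local temperature has
reached 103 deg C (376.15 K), which is what clamps the wet core near the
boiling plateau.  The spatial scheme is a conservative finite-volume
(flux-form) discretization on a node-centred grid with half cells at the
boundaries, so the discrete water-mass and energy balances telescope
exactly; the audits recorded in the time series measure genuine
conservation of the scheme, not discretization noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import properties
from .kinetics import KineticState, advance_kinetics
from .observables import Snapshot, TimeSeries, probe_indices
from .params import FryingSchedule, ModelParameters, NumericsConfig

__all__ = [
    "Grid2D",
    "FieldState",
    "SolverError",
    "gate_s_W",
    "evaporation_rate",
    "bath_temperature",
    "step_heat",
    "step_moisture",
    "simulate",
    "SimulationResult",
]

logger = logging.getLogger(__name__)

ALL_CONVECTIVE_FACES = ("east", "south", "north")

KELVIN = 273.15


class SolverError(RuntimeError):
    """Raised when a linear solve fails (singular system etc.)."""


@dataclass(frozen=True, eq=False)
class Grid2D:
    """Uniform node-centred grid on the half-width domain [0, W/2] x [0, H].

    ``x[0] = 0`` is the symmetry plane; ``x[-1] = W/2``, ``y[0] = 0`` and
    ``y[-1] = H`` are the convective boundaries.  Fields are stored with
    shape ``(ny, nx)`` indexed ``[j, i]`` for node (x_i, y_j).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    x: np.ndarray
    y: np.ndarray
    wx: np.ndarray          # control-volume widths in x (dx, half at edges)
    wy: np.ndarray
    cell_areas: np.ndarray  # (ny, nx), outer(wy, wx)

    @classmethod
    def make(cls, W: float, H: float, nx: int, ny: int) -> "Grid2D":
        if nx < 3 or ny < 3:
            raise ValueError("nx and ny must be >= 3")
        dx = (W / 2.0) / (nx - 1)
        dy = H / (ny - 1)
        x = np.linspace(0.0, W / 2.0, nx)
        y = np.linspace(0.0, H, ny)
        wx = np.full(nx, dx)
        wx[0] = wx[-1] = dx / 2.0
        wy = np.full(ny, dy)
        wy[0] = wy[-1] = dy / 2.0
        return cls(nx, ny, dx, dy, x, y, wx, wy, np.outer(wy, wx))

    @classmethod
    def from_params(cls, p: ModelParameters, n: NumericsConfig) -> "Grid2D":
        return cls.make(p.W, p.H, n.nx, n.ny)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def node_index(self, j, i):
        return j * self.nx + i


@dataclass
class FieldState:
    """All nodal fields at one instant: time, temperature, water, kinetics."""

    t: float
    T: np.ndarray                 # K, (ny, nx)
    C_w: np.ndarray               # mol/m^3, (ny, nx)
    kinetics: KineticState

    @classmethod
    def initial(cls, p: ModelParameters, grid: Grid2D) -> "FieldState":
        shape = (grid.ny, grid.nx)
        return cls(
            t=0.0,
            T=np.full(shape, p.T_i),
            C_w=np.full(shape, p.C_wi),
            kinetics=KineticState.initial(p.C_Ai, shape),
        )

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.T.copy(), self.C_w.copy(),
                          self.kinetics.copy())


# --------------------------------------------------------------------------
# gates, sinks, schedule

def gate_s_W(T, p: ModelParameters, smoothing_K: float = 0.0):
    """Evaporation gate: 0 below ``p.T_evap`` (376.15 K), 1 at or above."""
    T = np.asarray(T, dtype=float)
    if smoothing_K > 0.0:
        out = np.clip((T - p.T_evap) / smoothing_K + 0.5, 0.0, 1.0)
    else:
        out = (T >= p.T_evap).astype(float)
    return out if out.ndim else float(out)


def evaporation_rate(C_w, T, p: ModelParameters, smoothing_K: float = 0.0):
    """Volumetric water vaporization rate ``S_W * k_evp * C_w``, mol/(m^3 s)."""
    C_w = np.asarray(C_w, dtype=float)
    if np.any(C_w < 0):
        raise ValueError("water concentration must be >= 0")
    out = gate_s_W(T, p, smoothing_K) * p.k_evp * C_w
    return out if out.ndim else float(out)


def bath_temperature(t: float, s: FryingSchedule) -> float:
    """Oil-bath temperature (K) at time ``t`` under the step schedule.

    The step factor multiplies the ABSOLUTE temperature: after ``t_H`` the
    bath is ``f * T_fry`` kelvin (f = 0.95489 maps 170 deg C to 150.0 deg C).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return s.T_fry if t < s.t_H else s.f * s.T_fry


# --------------------------------------------------------------------------
# implicit finite-volume diffusion step

class _DiffusionOperator:
    """Backward-Euler solver for  cap * du/dt = div(gamma grad u) + BCs - sink.

    Conservative flux form on the node-centred grid: interior faces carry
    ``gamma_face * (u_nb - u) / h * L_face`` with arithmetic-mean face
    coefficients; convective faces carry ``robin * (ambient - u) * L_face``;
    the symmetry plane (any face not listed in ``faces``) carries zero flux.
    The resulting system is symmetric positive definite with bandwidth nx,
    so each step is one banded Cholesky solve (LAPACK ``pbsv``).
    """

    def __init__(self, grid: Grid2D, faces: tuple[str, ...] = ALL_CONVECTIVE_FACES):
        self.grid = grid
        self.faces = tuple(faces)
        nx, ny = grid.nx, grid.ny
        self.N = nx * ny

        robin_nodes = []
        robin_L = []
        if "east" in self.faces:
            robin_nodes.append(np.arange(ny) * nx + (nx - 1))
            robin_L.append(grid.wy)
        if "west" in self.faces:
            robin_nodes.append(np.arange(ny) * nx)
            robin_L.append(grid.wy)
        if "south" in self.faces:
            robin_nodes.append(np.arange(nx))
            robin_L.append(grid.wx)
        if "north" in self.faces:
            robin_nodes.append((ny - 1) * nx + np.arange(nx))
            robin_L.append(grid.wx)
        if robin_nodes:
            self.robin_nodes = np.concatenate(robin_nodes)
            self.robin_L = np.concatenate(robin_L)
        else:
            self.robin_nodes = np.zeros(0, dtype=int)
            self.robin_L = np.zeros(0)

    def step(self, u_old: np.ndarray, cap: np.ndarray, gamma: np.ndarray,
             robin, ambient: float, sink: np.ndarray,
             dt: float) -> np.ndarray:
        """One backward-Euler step; returns the new field (ny, nx)."""
        g = self.grid
        nx, ny, N = g.nx, g.ny, self.N
        cap_v = cap * g.cell_areas / dt

        # face conductances: arithmetic-mean coefficient * face length / spacing
        cx = 0.5 * (gamma[:, :-1] + gamma[:, 1:]) * g.wy[:, None] / g.dx
        cy = 0.5 * (gamma[:-1, :] + gamma[1:, :]) * g.wx[None, :] / g.dy

        diag = cap_v.copy()
        diag[:, :-1] += cx
        diag[:, 1:] += cx
        diag[:-1, :] += cy
        diag[1:, :] += cy
        diag = diag.ravel()
        rb = robin * self.robin_L
        if rb.size:
            np.add.at(diag, self.robin_nodes, rb)

        off1 = np.zeros((ny, nx))
        off1[:, :-1] = -cx                   # coupling (n, n+1) within a row
        offnx = np.zeros((ny, nx))
        offnx[:-1, :] = -cy                  # coupling (n, n+nx)

        # symmetric banded (upper) storage for LAPACK pbsv
        ab = np.zeros((nx + 1, N))
        ab[nx, :] = diag
        ab[nx - 1, 1:] = off1.ravel()[:-1]
        ab[0, nx:] = offnx.ravel()[:-nx]

        b = cap_v.ravel() * u_old.ravel() - (sink * g.cell_areas).ravel()
        if rb.size:
            # corner nodes appear once per convective face; accumulate both
            np.add.at(b, self.robin_nodes, rb * ambient)
        try:
            u_new = sla.solveh_banded(ab, b, lower=False,
                                      overwrite_ab=True, overwrite_b=True,
                                      check_finite=False)
        except Exception as exc:  # pragma: no cover - singular systems
            raise SolverError(f"implicit diffusion solve failed: {exc}") from exc
        if not np.all(np.isfinite(u_new)):
            raise SolverError("implicit diffusion solve produced non-finite values")
        return u_new.reshape(ny, nx)

    def boundary_flux_in(self, u: np.ndarray, robin: float,
                         ambient: float) -> float:
        """Total convective inflow  sum robin*(ambient - u_surface)*L  (per unit depth)."""
        if not self.robin_nodes.size:
            return 0.0
        us = u.ravel()[self.robin_nodes]
        return float(np.sum(robin * (ambient - us) * self.robin_L))


def _default_property_fn(p: ModelParameters, n: NumericsConfig):
    """Build the (rho_e, cp_e [J/(kg K)], kappa_e) evaluator for the solver.

    Default (``n.update_composition`` true): the water mass fraction is
    re-derived locally from the water concentration,
    ``omega_w = C_w * M_W / rho_e(T_i)``, while the solid fractions stay at
    their initial values and the mass-fraction mixing sums are NOT
    renormalized.  Initially this reduces to the nominal composition
    (omega_w = 0.773 vs the stated 0.772); as a region dries its effective
    conductivity and heat capacity collapse toward the sparse solid
    contribution (kappa_e ~ 0.06-0.2 W/(m K)), which is what lets a dried
    crust decouple the surface from the interior boiling plateau — the
    "heat insulation layer" regime of real frying.

    With ``update_composition`` false, properties use the fixed initial
    composition at local temperature only (no crust insulation forms).
    """
    comp = p.composition
    cset = n.property_coefficient_set

    if not n.update_composition:
        def props(T: np.ndarray, C_w: np.ndarray):
            T_C = T - KELVIN
            rho = properties.effective_density(T_C, comp, cset)
            cp = properties.effective_heat_capacity(T_C, comp, cset) * 1e3
            kap = properties.effective_conductivity(T_C, comp, cset)
            return rho, cp, kap
        return props

    rho_ref = properties.effective_density(p.T_i - KELVIN, comp, cset)
    wc, wp = comp.omega_carb, comp.omega_protein

    def props_local(T: np.ndarray, C_w: np.ndarray):
        T_C = T - KELVIN
        ww = np.clip(C_w * p.M_W / rho_ref, 0.0, 1.0)
        rho = (properties.component_density("water", T_C, cset) * ww
               + properties.component_density("carb", T_C, cset) * wc
               + properties.component_density("protein", T_C, cset) * wp)
        cp = (properties.component_heat_capacity("water", T_C, cset) * ww
              + properties.component_heat_capacity("carb", T_C, cset) * wc
              + properties.component_heat_capacity("protein", T_C, cset) * wp) * 1e3
        kap = (properties.component_conductivity("water", T_C, cset) * ww
               + properties.component_conductivity("carb", T_C, cset) * wc
               + properties.component_conductivity("protein", T_C, cset) * wp)
        return rho, cp, kap

    return props_local


def step_heat(state: FieldState, T_bath: float, dt: float, grid: Grid2D,
              p: ModelParameters, n: NumericsConfig | None = None,
              R_evp: np.ndarray | None = None,
              properties_fn=None,
              operator: _DiffusionOperator | None = None,
              faces: tuple[str, ...] = ALL_CONVECTIVE_FACES):
    """One implicit heat step; returns ``(T_new, audit)``.

    Effective properties are evaluated at the step-start temperature and
    frozen for the step; the evaporative sink ``R_evp * H_evp * M_W`` is
    explicit (step-start fields).  ``audit`` reports the boundary heat
    inflow, stored sensible heat, and latent sink over the step (J per unit
    strip length).
    """
    n = n or NumericsConfig()
    if properties_fn is None:
        properties_fn = _default_property_fn(p, n)
    if operator is None:
        operator = _DiffusionOperator(grid, faces)
    if R_evp is None:
        R_evp = evaporation_rate(state.C_w, state.T, p, n.gate_smoothing_K)

    rho, cp, kappa = properties_fn(state.T, state.C_w)
    cap = rho * cp
    sink = R_evp * p.H_evp * p.M_W          # W/m^3
    T_new = operator.step(state.T, cap, kappa, p.h_t, T_bath, sink, dt)

    audit = {
        "boundary_heat_in": operator.boundary_flux_in(T_new, p.h_t, T_bath) * dt,
        "stored_heat": float(np.sum(cap * grid.cell_areas * (T_new - state.T))),
        "latent_heat": float(np.sum(sink * grid.cell_areas)) * dt,
    }
    return T_new, audit


def step_moisture(state: FieldState, dt: float, grid: Grid2D,
                  p: ModelParameters, n: NumericsConfig | None = None,
                  R_evp: np.ndarray | None = None,
                  diffusivity_fn=None,
                  operator: _DiffusionOperator | None = None,
                  faces: tuple[str, ...] = ALL_CONVECTIVE_FACES):
    """One implicit moisture step; returns ``(C_w_new, audit)``.

    The Arrhenius diffusivity is evaluated at the state's current (already
    heat-stepped) temperature and frozen; the evaporation sink is explicit.
    The Robin condition drives the surface toward the bath-equilibrium
    concentration ``C_eq``.  Any negative concentrations (possible only
    through roundoff) are clipped to zero and the clipped amount reported.
    """
    n = n or NumericsConfig()
    if operator is None:
        operator = _DiffusionOperator(grid, faces)
    if R_evp is None:
        R_evp = evaporation_rate(state.C_w, state.T, p, n.gate_smoothing_K)
    if diffusivity_fn is None:
        D = properties.effective_diffusivity(state.T, p)
    else:
        D = diffusivity_fn(state.T)
    D = np.broadcast_to(np.asarray(D, dtype=float), state.T.shape)

    ones = np.ones_like(state.C_w)
    C_new = operator.step(state.C_w, ones, D, p.k_m, p.C_eq, R_evp, dt)

    clipped = 0.0
    if np.any(C_new < 0):
        clipped = float(np.sum(-C_new[C_new < 0] *
                               grid.cell_areas[C_new < 0]))
        logger.debug("moisture step clipped %.3e mol/m of negative water", clipped)
        C_new = np.clip(C_new, 0.0, None)

    audit = {
        # inflow convention: negative = water leaving through the boundary
        "boundary_water_in": operator.boundary_flux_in(C_new, p.k_m, p.C_eq) * dt,
        "stored_water": float(np.sum(grid.cell_areas * (C_new - state.C_w))),
        "evaporated_water": float(np.sum(R_evp * grid.cell_areas)) * dt,
        "clipped_water": clipped,
    }
    return C_new, audit


# --------------------------------------------------------------------------
# orchestration

@dataclass
class SimulationResult:
    """Bundle returned by :func:`simulate`."""

    series: TimeSeries
    snapshots: list[Snapshot]
    final_state: FieldState
    audit_totals: dict[str, float] = field(default_factory=dict)


def simulate(p: ModelParameters, s: FryingSchedule,
             n: NumericsConfig | None = None,
             faces: tuple[str, ...] = ALL_CONVECTIVE_FACES,
             progress_every: float | None = None) -> SimulationResult:
    """Run one frying simulation; deterministic for identical inputs.

    Records observables every ``n.output_every`` seconds (plus t=0 and
    t_end) and captures full-field snapshots at ``n.snapshot_times``.
    """
    from . import observables as obs

    n = n or NumericsConfig()
    grid = Grid2D.from_params(p, n)
    state = FieldState.initial(p, grid)
    op = _DiffusionOperator(grid, faces)
    props_fn = _default_property_fn(p, n)

    n_steps = int(round(s.t_end / n.dt))
    record_every = max(1, int(round(n.output_every / n.dt)))
    snap_steps = sorted(
        {min(n_steps, max(0, int(round(ts / n.dt)))) for ts in n.snapshot_times}
    )

    max_bath = s.T_fry  # f <= 1, so the pre-step bath is the hottest

    cum = {
        "boundary_heat_in": 0.0, "stored_heat": 0.0, "latent_heat": 0.0,
        "boundary_water_in": 0.0, "stored_water": 0.0,
        "evaporated_water": 0.0, "clipped_water": 0.0,
    }
    water_initial = float(np.sum(state.C_w * grid.cell_areas))

    records: list[list[float]] = []

    def record(st: FieldState) -> None:
        T_sfc, T_core = obs.probe_temperatures(st, grid)
        w = grid.cell_areas
        T_avg = float(np.sum(st.T * w) / np.sum(w)) - KELVIN
        # water balance: -(stored) should equal out through boundary + evaporated
        mass_res = (
            -cum["stored_water"] + cum["boundary_water_in"]
            - cum["evaporated_water"] + cum["clipped_water"]
        ) / water_initial
        heat_in = cum["boundary_heat_in"]
        energy_res = (
            (heat_in - cum["stored_heat"] - cum["latent_heat"])
            / max(abs(heat_in), 1e-30)
        )
        records.append([
            st.t,
            obs.average_water_percent(st, p, grid, n.property_coefficient_set),
            obs.average_acrylamide_ugkg(st, p, grid, n.property_coefficient_set),
            T_sfc,
            T_core,
            T_avg,
            mass_res,
            energy_res,
        ])

    snapshots: list[Snapshot] = []

    def snap(st: FieldState) -> None:
        snapshots.append(Snapshot(
            t=st.t, x=grid.x.copy(), y=grid.y.copy(), T=st.T.copy(),
            C_w=st.C_w.copy(), kinetics=st.kinetics.copy(),
        ))

    record(state)
    if 0 in snap_steps:
        snap(state)

    for step in range(1, n_steps + 1):
        t_new = step * n.dt
        try:
            T_bath = bath_temperature(t_new, s)
            R_evp = evaporation_rate(state.C_w, state.T, p, n.gate_smoothing_K)
            T_new, h_audit = step_heat(
                state, T_bath, n.dt, grid, p, n,
                R_evp=R_evp, properties_fn=props_fn, operator=op,
            )
            state.T = T_new
            C_new, m_audit = step_moisture(
                state, n.dt, grid, p, n,
                R_evp=R_evp, operator=op,
            )
            state.C_w = C_new
            state.kinetics = advance_kinetics(
                state.kinetics, state.T, n.dt, p, n.gate_smoothing_K
            )
        except SolverError as exc:
            raise SolverError(f"at t = {t_new:.3f} s (step {step}): {exc}") from exc
        state.t = t_new
        for key, val in h_audit.items():
            cum[key] += val
        for key, val in m_audit.items():
            cum[key] += val

        if state.T.max() > max_bath + 1e-6:
            logger.warning("maximum principle violated at t=%.2f s: T_max=%.3f K",
                           t_new, state.T.max())
        if step % record_every == 0 or step == n_steps:
            record(state)
        if step in snap_steps:
            snap(state)
        if progress_every and t_new % progress_every < n.dt / 2:
            logger.info("t = %6.1f s  T_max = %6.1f K", t_new, state.T.max())

    cols = [np.asarray(c) for c in zip(*records)]
    series = TimeSeries(*cols)
    return SimulationResult(series=series, snapshots=snapshots,
                            final_state=state, audit_totals=dict(cum))
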