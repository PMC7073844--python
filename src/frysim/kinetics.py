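"""Threshold-gated series-reaction kinetics of acrylamide.

Reducing sugar (A) converts to acrylamide (AA) which degrades to
melanoidin-type products (D):

    A --k1--> AA --k2--> D

Both rate constants are Arrhenius in absolute temperature and share one
pre-exponential factor ``k0``; both are multiplied by a Heaviside gate that
switches the chemistry on only at or above 120 deg C (393.15 K), the
threshold below which Maillard acrylamide formation is negligible.  The
formation step is first-order in reducing sugar alone — asparagine is
assumed non-limiting and is not tracked.

The per-time-step update uses the EXACT constant-temperature solution of the
linear ODE system rather than an Euler step: k2 is of order 0.07 1/s at bath
temperature, so an explicit step at dt ~ 0.1 s would be visibly inaccurate,
while the exact update makes the kinetics entirely insensitive to dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "KineticState",
    "gate_s_AA",
    "rate_constants",
    "advance_kinetics",
    "kinetics_closed_form",
]

# below this relative separation of k1 and k2 the repeated-root limit is used
_REPEATED_ROOT_RTOL = 1e-10


@dataclass
class KineticState:
    """Nodal concentrations (mol/m^3) of the A -> AA -> D chain.

    ``C_D`` is pure bookkeeping: it closes the stoichiometric balance
    C_A + C_AA + C_D = C_Ai exactly, per node.
    """

    C_A: np.ndarray
    C_AA: np.ndarray
    C_D: np.ndarray

    @classmethod
    def initial(cls, C_Ai: float, shape: tuple[int, ...]) -> "KineticState":
        return cls(
            C_A=np.full(shape, float(C_Ai)),
            C_AA=np.zeros(shape),
            C_D=np.zeros(shape),
        )

    def copy(self) -> "KineticState":
        return KineticState(self.C_A.copy(), self.C_AA.copy(), self.C_D.copy())

    @property
    def total(self) -> np.ndarray:
        return self.C_A + self.C_AA + self.C_D


def gate_s_AA(T, p: ModelParameters, smoothing_K: float = 0.0):
    """Acrylamide gate: 0 below ``p.T_AA``, 1 at or above (inclusive).

    With ``smoothing_K > 0`` the Heaviside is replaced by a linear ramp of
    that width centred on the threshold (for sensitivity analysis only).
    """
    T = np.asarray(T, dtype=float)
    if smoothing_K > 0.0:
        out = np.clip((T - p.T_AA) / smoothing_K + 0.5, 0.0, 1.0)
    else:
        out = (T >= p.T_AA).astype(float)
    return out if out.ndim else float(out)


def rate_constants(T, p: ModelParameters, smoothing_K: float = 0.0):
    """Gated Arrhenius rate constants (k1, k2), 1/s, at temperature T (K).

    k1 (formation, Ea_AA) and k2 (degradation, Ea_D) share the single
    pre-exponential p.k0 and the same on/off gate.
    """
    T = np.asarray(T, dtype=float)
    gate = gate_s_AA(T, p, smoothing_K)
    k1 = gate * p.k0 * np.exp(-p.Ea_AA / (p.R_g * T))
    k2 = gate * p.k0 * np.exp(-p.Ea_D / (p.R_g * T))
    if np.ndim(gate) == 0:
        return float(k1), float(k2)
    return k1, k2


def kinetics_closed_form(C_A0: float, k1: float, k2: float, t: float):
    """Analytic series-reaction solution (C_A, C_AA) at time t, from C_AA0=0.

    The textbook result C_AA = C_A0 k1 (e^{-k1 t} - e^{-k2 t})/(k2 - k1),
    with the repeated-root limit C_A0 k1 t e^{-k1 t} when k1 == k2.  Serves
    as the independent oracle for :func:`advance_kinetics` composed over
    many steps.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    C_A = C_A0 * np.exp(-k1 * t)
    scale = max(abs(k1), abs(k2), 1.0)
    if abs(k2 - k1) <= _REPEATED_ROOT_RTOL * scale:
        C_AA = C_A0 * k1 * t * np.exp(-k1 * t)
    else:
        C_AA = C_A0 * k1 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
    return float(C_A), float(C_AA)


def advance_kinetics(
    state: KineticState,
    T,
    dt: float,
    p: ModelParameters,
    smoothing_K: float = 0.0,
) -> KineticState:
    """Advance the A -> AA -> D chain by ``dt`` seconds at frozen temperature.

    Applies the exact constant-T solution nodewise; ``T`` may be a scalar or
    an array broadcastable against the state.  The degraded pool C_D absorbs
    whatever the balance requires, so C_A + C_AA + C_D is conserved to
    machine precision.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    k1, k2 = rate_constants(T, p, smoothing_K)
    k1 = np.broadcast_to(np.asarray(k1, dtype=float), state.C_A.shape)
    k2 = np.broadcast_to(np.asarray(k2, dtype=float), state.C_A.shape)

    E1 = np.exp(-k1 * dt)
    E2 = np.exp(-k2 * dt)
    C_A_new = state.C_A * E1

    dk = k2 - k1
    scale = np.maximum(np.maximum(np.abs(k1), np.abs(k2)), 1.0)
    repeated = np.abs(dk) <= _REPEATED_ROOT_RTOL * scale
    dk_safe = np.where(repeated, 1.0, dk)
    transfer = np.where(
        repeated,
        k1 * state.C_A * dt * E1,
        k1 * state.C_A * (E1 - E2) / dk_safe,
    )
    C_AA_new = state.C_AA * E2 + transfer
    # close the balance exactly: everything that left A and AA lands in D
    C_D_new = state.C_D + (state.C_A - C_A_new) - (C_AA_new - state.C_AA)
    return KineticState(C_A_new, C_AA_new, C_D_new)
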