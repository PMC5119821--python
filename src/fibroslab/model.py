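"""Three-variable (Fenton–Karma) membrane model.

The model describes the transmembrane potential ``V`` (normalized, resting
near 0, plateau near 1) together with two gate variables ``v`` (fast,
sodium-like inactivation) and ``w`` (slow, calcium-like inactivation).
Three phenomenological currents drive ``V``:

* a fast inward current ``I_fi`` gated by ``v`` and switched on above the
  depolarization threshold ``V_c``,
* a slow outward (repolarizing) current ``I_so``,
* a slow inward (plateau) current ``I_si`` gated by ``w`` through a smooth
  ``tanh`` switch around ``V_c_si``.

The excitability parameter ``tau_d`` (activation time constant of the fast
inward current) is the single dial used to emulate electrical remodeling:
larger ``tau_d`` means lower excitability, shorter action potentials and
slower conduction.

All rates are per millisecond; voltages are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "FKParameters",
    "MembraneState",
    "resting_state",
    "compute_currents",
    "gate_derivatives",
    "reaction_step",
]


@dataclass(frozen=True)
class FKParameters:
    """Parameter set of the three-current membrane model.

    Defaults are the modified-Beeler-Reuter-like set used for all
    simulations in this package. ``tau_d`` is the remodeling dial:
    0.25 ms (normal), 0.30 ms (intermediate), 0.35 ms (strong remodeling).
    """

    tau_d: float = 0.25  # ms, fast-inward activation (excitability)
    tau_v_plus: float = 3.33  # ms, fast-gate closing
    tau_v1_minus: float = 19.6  # ms, fast-gate reopening below V_v
    tau_v2_minus: float = 1000.0  # ms, fast-gate reopening above V_v
    tau_w_plus: float = 667.0  # ms, slow-gate closing
    tau_w_minus: float = 11.0  # ms, slow-gate reopening
    tau_o: float = 8.3  # ms, resting outward decay
    tau_r: float = 50.0  # ms, plateau repolarization
    tau_si: float = 45.0  # ms, slow-inward time scale
    k: float = 10.0  # tanh steepness of the slow-inward switch
    V_c_si: float = 0.85  # slow-inward switch midpoint
    V_c: float = 0.13  # depolarization threshold
    V_v: float = 0.055  # fast-gate recovery-rate switch

    def __post_init__(self) -> None:
        for name in (
            "tau_d", "tau_v_plus", "tau_v1_minus", "tau_v2_minus",
            "tau_w_plus", "tau_w_minus", "tau_o", "tau_r", "tau_si",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.V_v < self.V_c < self.V_c_si < 1.0):
            raise ValueError("thresholds must satisfy 0 < V_v < V_c < V_c_si < 1")

    def with_tau_d(self, tau_d: float) -> "FKParameters":
        return replace(self, tau_d=tau_d)


@dataclass
class MembraneState:
    """Pointwise state (V, v, w); fields may be scalars or ndarrays."""

    V: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def copy(self) -> "MembraneState":
        return MembraneState(np.copy(self.V), np.copy(self.v), np.copy(self.w))


def resting_state(shape=()) -> MembraneState:
    """Quiescent tissue: V = 0 with both gates fully recovered (v = w = 1)."""
    return MembraneState(
        V=np.zeros(shape), v=np.ones(shape), w=np.ones(shape)
    )


def _check_finite(state: MembraneState) -> None:
    for name in ("V", "v", "w"):
        if not np.all(np.isfinite(getattr(state, name))):
            raise ValueError(f"non-finite values in membrane state field {name!r}")


def compute_currents(
    state: MembraneState, params: FKParameters
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (I_fi, I_so, I_si) in 1/ms.

    The depolarization switch is the Heaviside step p = θ(V − V_c) with the
    convention θ(0) = 1 (fixed throughout the package).
    """
    _check_finite(state)
    V, v, w = state.V, state.v, state.w
    p = np.where(V >= params.V_c, 1.0, 0.0)
    I_fi = -v * p * (V - params.V_c) * (1.0 - V) / params.tau_d
    I_so = V * (1.0 - p) / params.tau_o + p / params.tau_r
    I_si = -w * (1.0 + np.tanh(params.k * (V - params.V_c_si))) / (2.0 * params.tau_si)
    return I_fi, I_so, I_si


def gate_derivatives(
    state: MembraneState, params: FKParameters
) -> Tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dv/dt, dw/dt) in 1/ms.

    The fast-gate recovery time constant is voltage dependent,
    τ_v⁻(V) = (1 − q)·τ_v1⁻ + q·τ_v2⁻ with q = θ(V − V_v): recovery is fast
    (τ_v1⁻) once the potential has fallen below V_v and slow (τ_v2⁻) in
    between V_v and V_c. The slow gate uses a constant τ_w⁻.
    """
    _check_finite(state)
    V, v, w = state.V, state.v, state.w
    p = np.where(V >= params.V_c, 1.0, 0.0)
    q = np.where(V >= params.V_v, 1.0, 0.0)
    tau_v_minus = (1.0 - q) * params.tau_v1_minus + q * params.tau_v2_minus
    dv = (1.0 - p) * (1.0 - v) / tau_v_minus - p * v / params.tau_v_plus
    dw = (1.0 - p) * (1.0 - w) / params.tau_w_minus - p * w / params.tau_w_plus
    return dv, dw


def _derivatives(state: MembraneState, params: FKParameters):
    I_fi, I_so, I_si = compute_currents(state, params)
    dv, dw = gate_derivatives(state, params)
    return -(I_fi + I_so + I_si), dv, dw


def reaction_step(
    state: MembraneState, params: FKParameters, dt: float = 0.0165
) -> MembraneState:
    """Advance an uncoupled membrane patch by one explicit midpoint (RK2) step.

    Both stages re-evaluate the Heaviside switches. Heun's method agrees
    with the midpoint rule to well below the solver tolerance for this
    model (see the test suite); the midpoint rule is the package default.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    dV1, dv1, dw1 = _derivatives(state, params)
    mid = MembraneState(
        state.V + 0.5 * dt * dV1,
        state.v + 0.5 * dt * dv1,
        state.w + 0.5 * dt * dw1,
    )
    dV2, dv2, dw2 = _derivatives(mid, params)
    return MembraneState(
        state.V + dt * dV2,
        state.v + dt * dv2,
        state.w + dt * dw2,
    )
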