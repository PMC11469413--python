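"""Lyapunov energy of the identity-recurrence circuit near its fixed point.

Near the normalization fixed point the circuit behaves like a coupled
damped harmonic oscillator Iẍ + B̃ẋ + Kx = 0 in the coordinate x = δy,
with diagonal stiffness K = D(a_s ⊘ (τy⊙τa)).  The classical Lyapunov
function of such a system with a diagonal witness C (CB̃ + B̃ᵀC ≻ 0,
CK = KC symmetric) is V = ẋᵀCẋ + xᵀCKx, whose derivative along the flow
is −ẋᵀ(CB̃ + B̃ᵀC)ẋ ≤ 0.  Pulling τy⊙ẏ = −(⌊a⌋⊙y − b⊙z) back through the
circuit's own equation gives the energy in circuit variables,

    V(y, a) = Σᵢ cᵢ · [ (aᵢyᵢ − bᵢzᵢ)²  +  (τyᵢ/τaᵢ)·a_sᵢ·(yᵢ − y_sᵢ)² ]

with weights cᵢ = tᵢ·a_sᵢ²/y_sᵢ², where tᵢ is the diagonal Lyapunov
witness of the damping matrix B.  Eliminating δa from the linearized
equations shows δy obeys δÿ + B°δẏ + Kδy = 0 with B° = ΔBΔ⁻¹ for
Δ = D(y_s ⊘ (τy⊙a_s)); in the coordinate x = Δ⁻¹δy the damping is
exactly B, and V above is the pullback of ẋᵀTẋ + xᵀTKx, so
V̇ = −ẋᵀ(TB + BᵀT)ẋ ≤ 0 holds exactly along the linearized flow (the
test suite checks this as a matrix inequality).  The first term penalizes
the residual of the instantaneously reconstructed gated input drive
(input matching); the second penalizes deviation of the principal
neuron's response from its divisively-normalized steady state.  Weaker
inputs weight input matching more; stronger inputs increasingly engage
the normalization objective.

At n = 1 the bracket reduces (up to the positive constant c) exactly to

    V(y, a) = (τy/τa)·sqrt(b0²σ² + w b²z²)·(y − bz/sqrt(b0²σ² + w b²z²))²
              + (a y − b z)².

V vanishes exactly at the fixed point, is positive in a punctured
neighborhood, and is non-increasing along the linearized flow; along the
full nonlinear flow it decays to zero as the state converges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fixed_points import analytic_fixed_point
from .params import CircuitParams, CircuitState
from .stability import qep_matrices, splitting_certificate

__all__ = ["EnergyEvaluation", "energy_identity", "energy_2d", "lyapunov_weights",
           "energy_quadratic"]


@dataclass
class EnergyEvaluation:
    """Energy value with its per-neuron decomposition."""

    V: float
    matching_terms: np.ndarray        # cᵢ·(aᵢyᵢ − bᵢzᵢ)²
    normalization_terms: np.ndarray   # cᵢ·(τyᵢ/τaᵢ)·a_sᵢ·(yᵢ − y_sᵢ)²
    weights: np.ndarray               # cᵢ


def lyapunov_weights(params: CircuitParams, z: np.ndarray,
                     T_diag: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-neuron energy weights cᵢ = tᵢ·a_sᵢ²/y_sᵢ² (tᵢ from the M-matrix witness).

    Channels with zero input drive (y_sᵢ = 0) have no defined oscillator
    coordinate; their terms are skipped (weight 0) with a warning.
    """
    if T_diag is None:
        T_diag = splitting_certificate(qep_matrices(params, z)).T_diag
    fp = analytic_fixed_point(params, z)
    live = np.abs(fp.y_s) > 0
    if not np.all(live):
        warnings.warn("zero-input channels have no energy term; skipped", stacklevel=2)
    c = np.zeros(params.n)
    c[live] = np.asarray(T_diag, dtype=float)[live] * fp.a_s[live] ** 2 / fp.y_s[live] ** 2
    return c


def energy_identity(params: CircuitParams, z: np.ndarray, state: CircuitState,
                    T_diag: Optional[np.ndarray] = None) -> EnergyEvaluation:
    """Evaluate the n-dimensional energy at a state (requires W_r = I).

    Channels with zero input drive (y_sᵢ = 0) are well-defined here: the
    weights involve a_sᵢ², never 1/y_sᵢ².
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    fp = analytic_fixed_point(params, z)
    c = lyapunov_weights(params, z, T_diag)
    matching = c * (state.a * state.y - params.b * z) ** 2
    normalization = c * (params.tau_y / params.tau_a) * fp.a_s * (state.y - fp.y_s) ** 2
    V = float(np.sum(matching) + np.sum(normalization))
    return EnergyEvaluation(V=V, matching_terms=matching,
                            normalization_terms=normalization, weights=c)


def energy_quadratic(params: CircuitParams, z: np.ndarray, dy: np.ndarray, da: np.ndarray,
                     T_diag: Optional[np.ndarray] = None) -> float:
    """Quadratic form of the energy on a perturbation (δy, δa).

    This is the exact Lyapunov function of the linearized system:
    V = Σᵢ cᵢ·[(a_s⊙δy + y_s⊙δa)ᵢ² + (τy⊘τa ⊙ a_s)ᵢ·δyᵢ²], monotonically
    non-increasing along the linearized flow.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    fp = analytic_fixed_point(params, z)
    c = lyapunov_weights(params, z, T_diag)
    dy = np.asarray(dy, dtype=float)
    da = np.asarray(da, dtype=float)
    lin_match = (fp.a_s * dy + fp.y_s * da) ** 2               # (τy·δẏ)²
    lin_norm = (params.tau_y / params.tau_a) * fp.a_s * dy**2
    return float(np.sum(c * (lin_match + lin_norm)))


def energy_2d(params: CircuitParams, z: float, state: CircuitState) -> EnergyEvaluation:
    """The damped-harmonic-oscillator energy of the 2D circuit (n = 1)."""
    if params.n != 1:
        raise ValueError("energy_2d requires n = 1")
    z = float(np.asarray(z).reshape(()))
    b, b0, sig = params.b[0], params.b0[0], params.sigma[0]
    w = params.W[0, 0]
    ty, ta = params.tau_y[0], params.tau_a[0]
    a_s = np.sqrt((b0 * sig) ** 2 + w * (b * z) ** 2)
    y, a = state.y[0], state.a[0]
    normalization = (ty / ta) * a_s * (y - b * z / a_s) ** 2
    matching = (a * y - b * z) ** 2
    return EnergyEvaluation(V=float(matching + normalization),
                            matching_terms=np.array([matching]),
                            normalization_terms=np.array([normalization]),
                            weights=np.array([1.0]))
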