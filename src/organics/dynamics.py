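"""Right-hand sides of the three dynamical variants of the circuit.

All three share the modulator equation

    τa ⊙ ȧ = −a + sqrt(b0²⊙σ² + W(y² ⊙ ⌊a⌋²))

whose square-root argument is bounded below by b0²⊙σ² > 0 because W is
nonnegative, so the dynamics are globally defined.  The variants differ in
the principal-neuron equation:

* identity recurrence (W_r = I, simplified using y⁺−y⁻ = y):
      τy ⊙ ẏ = −⌊a⌋ ⊙ y + b ⊙ z
* general recurrence:
      τy ⊙ ẏ = −y + b ⊙ z + (1 − ⌊a⌋) ⊙ (W_r y)
* rectified recurrence (recurrent drive through the rectified rate ⌊y⌋,
  keeping lateral input nonnegative):
      τy ⊙ ẏ = −y + b ⊙ z + (1 − ⌊a⌋) ⊙ (W_r ⌊y⌋)

With W_r = I the general form collapses exactly onto the identity form:
−y + (1 − ⌊a⌋)y = −⌊a⌋y.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .params import CircuitParams, CircuitState, rectify

__all__ = [
    "rhs_identity",
    "rhs_general",
    "rhs_rectified",
    "get_rhs",
    "modulator_drive",
    "VARIANTS",
]


def modulator_drive(y: np.ndarray, a: np.ndarray, params: CircuitParams) -> np.ndarray:
    """sqrt(b0²⊙σ² + W(y² ⊙ ⌊a⌋²)): the depolarization target of the a neurons."""
    arg = (params.b0 * params.sigma) ** 2 + params.W @ (y**2 * rectify(a) ** 2)
    return np.sqrt(arg)


def _a_dot(y: np.ndarray, a: np.ndarray, params: CircuitParams) -> np.ndarray:
    return (-a + modulator_drive(y, a, params)) / params.tau_a


def rhs_identity(state: CircuitState, params: CircuitParams, z: np.ndarray) -> CircuitState:
    """Time derivative (ẏ, ȧ) of the identity-recurrence circuit."""
    z = np.asarray(z, dtype=float)
    y_dot = (-rectify(state.a) * state.y + params.b * z) / params.tau_y
    return CircuitState(y=y_dot, a=_a_dot(state.y, state.a, params))


def rhs_general(state: CircuitState, params: CircuitParams, z: np.ndarray) -> CircuitState:
    """Time derivative (ẏ, ȧ) with arbitrary recurrent weights W_r."""
    z = np.asarray(z, dtype=float)
    recur = (1.0 - rectify(state.a)) * (params.W_r @ state.y)
    y_dot = (-state.y + params.b * z + recur) / params.tau_y
    return CircuitState(y=y_dot, a=_a_dot(state.y, state.a, params))


def rhs_rectified(state: CircuitState, params: CircuitParams, z: np.ndarray) -> CircuitState:
    """Time derivative (ẏ, ȧ) with the recurrent drive rectified (W_r ⌊y⌋)."""
    z = np.asarray(z, dtype=float)
    recur = (1.0 - rectify(state.a)) * (params.W_r @ rectify(state.y))
    y_dot = (-state.y + params.b * z + recur) / params.tau_y
    return CircuitState(y=y_dot, a=_a_dot(state.y, state.a, params))


VARIANTS: dict[str, Callable[[CircuitState, CircuitParams, np.ndarray], CircuitState]] = {
    "identity": rhs_identity,
    "general": rhs_general,
    "rectified": rhs_rectified,
}


def get_rhs(variant: str) -> Callable[[CircuitState, CircuitParams, np.ndarray], CircuitState]:
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}") from None
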