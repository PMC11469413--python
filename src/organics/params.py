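"""Circuit parameterization, state containers, and firing-rate readouts.

The ORGaNICs circuit has two neuron types: principal (``y``) neurons that
carry the circuit's output, and modulator (``a``) neurons whose rectified
activity gates the recurrent drive (recurrent gain ``1 - a+``), dynamically
implementing the denominator of the divisive-normalization equation.  All
per-neuron constants are length-``n`` vectors; scalars broadcast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "CircuitParams",
    "CircuitState",
    "FiringRates",
    "rectify",
    "firing_rates",
    "input_drive",
]

ArrayLike = Union[float, int, list, np.ndarray]


def rectify(x: np.ndarray) -> np.ndarray:
    """Halfwave rectification ⌊x⌋ = max(x, 0), elementwise."""
    return np.maximum(x, 0.0)


def _as_vector(value: ArrayLike, n: int, name: str) -> np.ndarray:
    """Coerce a scalar or sequence to a float vector of length n."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected scalar or length-{n} vector, got shape {arr.shape}")
    return arr


def _as_matrix(value: ArrayLike, shape: tuple[int, int], name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(shape, float(arr))
    if arr.shape != shape:
        raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
    return arr


@dataclass
class CircuitParams:
    """All constants of one ORGaNICs circuit.

    Parameters
    ----------
    n : int
        Number of principal neurons (and of modulator neurons).
    tau_y, tau_a : array_like
        Intrinsic membrane time constants of the y and a neurons (ms),
        strictly positive.  Scalars broadcast to length ``n``.
    b, b0 : array_like
        Dimensionless input gains feeding the external drive to the y
        neurons (``b``) and the semisaturation to the a neurons (``b0``).
    sigma : array_like
        Semisaturation constants σ controlling response gain at low input
        contrast; they enter the normalization denominator as ``(b0·σ)²``.
    W_r : array_like
        n×n recurrent weight matrix between principal neurons.  The
        identity gives exact divisive normalization at steady state.
    W : array_like
        n×n nonnegative normalization-pool weights: which neurons'
        contrast energy divides each response.
    W_zx : array_like or None
        Optional n×m input-encoding weights; when absent the input drive
        is the raw input (requires m = n).
    """

    n: int
    tau_y: ArrayLike = 2.0
    tau_a: ArrayLike = 2.0
    b: ArrayLike = 1.0
    b0: ArrayLike = 1.0
    sigma: ArrayLike = 1.0
    W_r: ArrayLike = None
    W: ArrayLike = None
    W_zx: ArrayLike = None

    def __post_init__(self) -> None:
        n = int(self.n)
        if n < 1:
            raise ValueError("n must be a positive integer")
        self.n = n
        self.tau_y = _as_vector(self.tau_y, n, "tau_y")
        self.tau_a = _as_vector(self.tau_a, n, "tau_a")
        self.b = _as_vector(self.b, n, "b")
        self.b0 = _as_vector(self.b0, n, "b0")
        self.sigma = _as_vector(self.sigma, n, "sigma")
        self.W_r = np.eye(n) if self.W_r is None else _as_matrix(self.W_r, (n, n), "W_r")
        self.W = np.eye(n) if self.W is None else _as_matrix(self.W, (n, n), "W")
        if self.W_zx is not None:
            self.W_zx = np.asarray(self.W_zx, dtype=float)
            if self.W_zx.ndim != 2 or self.W_zx.shape[0] != n:
                raise ValueError(f"W_zx must be n×m with n={n}, got {np.shape(self.W_zx)}")
        for name in ("tau_y", "tau_a", "b", "b0", "sigma"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive elementwise")
        if np.any(self.W < 0):
            raise ValueError("normalization weights W must be nonnegative elementwise")
        for name in ("tau_y", "tau_a", "b", "b0", "sigma", "W_r", "W"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def m(self) -> int:
        """Input dimension (columns of W_zx; n when W_zx is absent)."""
        return self.n if self.W_zx is None else self.W_zx.shape[1]

    @property
    def identity_recurrence(self) -> bool:
        return bool(np.allclose(self.W_r, np.eye(self.n), atol=1e-12))

    # ---- JSON config round trip (scalars broadcast on load) ----

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "tau_y": self.tau_y.tolist(),
            "tau_a": self.tau_a.tolist(),
            "b": self.b.tolist(),
            "b0": self.b0.tolist(),
            "sigma": self.sigma.tolist(),
            "W_r": self.W_r.tolist(),
            "W": self.W.tolist(),
        }
        if self.W_zx is not None:
            d["W_zx"] = self.W_zx.tolist()
        return d

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        allowed = {"n", "tau_y", "tau_a", "b", "b0", "sigma", "W_r", "W", "W_zx"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n" not in d:
            raise ValueError("config must specify n")
        return cls(**d)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CircuitParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CircuitState:
    """Membrane potentials (relative to threshold, may be negative)."""

    y: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.y.shape != self.a.shape or self.y.ndim != 1:
            raise ValueError("y and a must be vectors of equal length")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.a))):
            raise ValueError("state contains non-finite entries")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class FiringRates:
    """Rectified-power firing rates of the complementary y± pair and a.

    ``y_plus = ⌊y⌋²`` and ``y_minus = ⌊−y⌋²`` are the rates of neurons with
    complementary (anti-phase) receptive fields — only one fires at a time,
    the sign of the shared membrane potential selecting which — so that
    ``y_plus − y_minus`` reconstructs the signed quantity ``y·|y|`` family
    identities ``y_plus ⊙ y_minus = 0`` and ``y_plus + y_minus = y²`` hold
    exactly.  ``a_plus = ⌊a⌋`` is the modulator rate.
    """

    y_plus: np.ndarray
    y_minus: np.ndarray
    a_plus: np.ndarray


def firing_rates(state: CircuitState) -> FiringRates:
    """Map membrane potentials to firing rates: y± = ⌊±y⌋², a⁺ = ⌊a⌋."""
    return FiringRates(
        y_plus=rectify(state.y) ** 2,
        y_minus=rectify(-state.y) ** 2,
        a_plus=rectify(state.a),
    )


def input_drive(x: np.ndarray, params: CircuitParams) -> np.ndarray:
    """Input drive z = W_zx · x (pass-through when W_zx is absent and m = n)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if params.W_zx is None:
        if x.shape[0] != params.n:
            raise ValueError(f"input length {x.shape[0]} != n={params.n} and no W_zx given")
        return x
    if x.shape[0] != params.W_zx.shape[1]:
        raise ValueError(f"input length {x.shape[0]} does not match W_zx columns {params.W_zx.shape[1]}")
    return params.W_zx @ x
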