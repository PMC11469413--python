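"""Steady states of the circuit.

For identity recurrent weights the normalization fixed point is known in
closed form,

    a_s = sqrt(b0²⊙σ² + W(b²⊙z²)),    y_s = (b⊙z) ⊘ a_s ,

and the steady-state firing rates ``y_s± = ⌊±b⊙z⌋² ⊘ a_s²`` follow the
divisive-normalization equation exactly when b = b0 = const·1.

For arbitrary recurrence the steady state is computed by an alternating
scheme in which each half-step is an exact linear solve:

  (i)  given a:  (I − D(1−⌊a⌋) W_r) y = b⊙z
  (ii) given y:  the modulator steady state with a > 0 satisfies
       a² = b0²⊙σ² + W(y²⊙a²), linear in q = a²:  (I − W D(y²)) q = b0²⊙σ²

initialized at the identity-recurrence closed form.  Under the usual
constraints (max singular value of W_r ≤ 1, ‖z‖ ≤ 1) it converges to
max-norm residual 1e−6 in a handful of outer iterations.

The 2D circuit (one y neuron, one a neuron) admits exhaustive enumeration:
every fixed point has a = b0σ/sqrt(1 − w·y²), which confines y to the
interval |y| < 1/√w (for w > 0), so a dense sign-change scan of the scalar
steady-state equation over that interval, followed by root polishing,
finds all fixed points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .dynamics import get_rhs, rhs_general, rhs_identity
from .params import CircuitParams, CircuitState, FiringRates, firing_rates, rectify

__all__ = [
    "FixedPointResult",
    "analytic_fixed_point",
    "normalization_response",
    "fixed_point_iteration",
    "find_fixed_points_2d",
    "refine_fixed_point",
]


@dataclass
class FixedPointResult:
    """A steady state plus solver metadata."""

    y_s: np.ndarray
    a_s: np.ndarray
    method: str                      # "analytic" | "iteration" | "root_find"
    n_iter: int = 0
    residual: float = 0.0            # max-norm of the RHS at (y_s, a_s)
    converged: bool = True
    stable: Optional[bool] = None    # None until classified (or marginal)
    max_real_eig: Optional[float] = None

    @property
    def rates(self) -> FiringRates:
        return firing_rates(self.state)

    @property
    def y_s_plus(self) -> np.ndarray:
        return rectify(self.y_s) ** 2

    @property
    def y_s_minus(self) -> np.ndarray:
        return rectify(-self.y_s) ** 2

    @property
    def a_s_plus(self) -> np.ndarray:
        return rectify(self.a_s)

    @property
    def state(self) -> CircuitState:
        return CircuitState(y=self.y_s.copy(), a=self.a_s.copy())

    def to_dict(self) -> dict:
        return {
            "y_s": self.y_s.tolist(),
            "a_s": self.a_s.tolist(),
            "y_s_plus": self.y_s_plus.tolist(),
            "y_s_minus": self.y_s_minus.tolist(),
            "a_s_plus": self.a_s_plus.tolist(),
            "method": self.method,
            "n_iter": self.n_iter,
            "residual": self.residual,
            "converged": self.converged,
            "stable": self.stable,
            "max_real_eig": self.max_real_eig,
        }


def _residual(params: CircuitParams, z: np.ndarray, y: np.ndarray, a: np.ndarray,
              variant: str = "general") -> float:
    """Max-norm of the RHS; infinite for iterates outside the representable range."""
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(a))):
        return np.inf
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            d = get_rhs(variant)(CircuitState(y=y, a=a), params, z)
    except ValueError:   # overflow inside the RHS evaluation
        return np.inf
    res = float(max(np.max(np.abs(d.y)), np.max(np.abs(d.a))))
    return res if np.isfinite(res) else np.inf


def analytic_fixed_point(params: CircuitParams, z: np.ndarray) -> FixedPointResult:
    """Closed-form normalization fixed point (requires W_r = I)."""
    if not params.identity_recurrence:
        raise ValueError("analytic fixed point requires identity recurrent weights W_r = I")
    z = np.atleast_1d(np.asarray(z, dtype=float))
    bz = params.b * z
    a_s = np.sqrt((params.b0 * params.sigma) ** 2 + params.W @ (bz**2))
    y_s = bz / a_s
    res = _residual(params, z, y_s, a_s, "identity")
    return FixedPointResult(y_s=y_s, a_s=a_s, method="analytic", n_iter=0, residual=res)


def normalization_response(params: CircuitParams, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady firing rates via the divisive-normalization equation.

    y_s± = ⌊±z⌋² ⊘ (σ² + W(⌊z⌋² + ⌊−z⌋²) / b0²-scaled pool); valid under
    the gain condition b = b0 = const·1, where it coincides exactly with
    the firing rates of the analytic fixed point.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    b0c = params.b0[0]
    if not (np.allclose(params.b, params.b[0]) and np.allclose(params.b0, b0c)
            and np.allclose(params.b, params.b0)):
        raise ValueError("normalization_response requires b = b0 = constant vector")
    contrast_energy = rectify(z) ** 2 + rectify(-z) ** 2   # = z²
    denom = params.sigma**2 + params.W @ contrast_energy
    return rectify(z) ** 2 / denom, rectify(-z) ** 2 / denom


def fixed_point_iteration(params: CircuitParams, z: np.ndarray, tol: float = 1e-8,
                          max_iter: int = 50) -> FixedPointResult:
    """Alternating exact-solve iteration for the steady state with general W_r.

    Each outer iteration solves the principal-neuron linear system given the
    modulator state, then the modulator quadratic (linear in a²) given the
    principal state.  Initialized at the identity-recurrence closed form.
    Returns the best iterate flagged ``converged=False`` on failure.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n = params.n
    bz = params.b * z
    v = (params.b0 * params.sigma) ** 2
    # identity-recurrence closed form as initial iterate
    a = np.sqrt(v + params.W @ (bz**2))
    y = bz / a
    best = (y, a, _residual(params, z, y, a))
    eye = np.eye(n)
    for k in range(1, max_iter + 1):
        try:
            y = np.linalg.solve(eye - (1.0 - rectify(a))[:, None] * params.W_r, bz)
        except np.linalg.LinAlgError:
            return FixedPointResult(y_s=best[0], a_s=best[1], method="iteration",
                                    n_iter=k, residual=best[2], converged=False)
        q = None
        try:
            q = np.linalg.solve(eye - params.W * (y**2)[None, :], v)
        except np.linalg.LinAlgError:
            pass
        if q is not None and np.all(q > 0):
            a = np.sqrt(q)
        else:
            # damped one-step map fallback (kept bounded by the sqrt)
            for _ in range(50):
                a_new = np.sqrt(v + params.W @ (y**2 * rectify(a) ** 2))
                if not np.all(np.isfinite(a_new)):
                    break
                if np.max(np.abs(a_new - a)) < 0.1 * tol:
                    a = a_new
                    break
                a = 0.5 * a + 0.5 * a_new
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(a))):
            return FixedPointResult(y_s=best[0], a_s=best[1], method="iteration",
                                    n_iter=k, residual=best[2], converged=False)
        res = _residual(params, z, y, a)
        if res < best[2]:
            best = (y, a, res)
        if res < tol:
            return FixedPointResult(y_s=y, a_s=a, method="iteration",
                                    n_iter=k, residual=res, converged=True)
    return FixedPointResult(y_s=best[0], a_s=best[1], method="iteration",
                            n_iter=max_iter, residual=best[2], converged=False)


def refine_fixed_point(params: CircuitParams, z: np.ndarray, y0: np.ndarray, a0: np.ndarray,
                       variant: str = "general", tol: float = 1e-10) -> FixedPointResult:
    """Polish a steady-state guess with a damped Newton solve on the full RHS."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    rhs = get_rhs(variant)
    n = params.n

    def fun(x):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                d = rhs(CircuitState(y=x[:n], a=x[n:]), params, z)
        except ValueError:
            return np.full(2 * n, 1e30)
        out = np.concatenate([d.y, d.a])
        return np.where(np.isfinite(out), out, 1e30)

    sol = optimize.root(fun, np.concatenate([y0, a0]), method="hybr", tol=1e-12)
    y, a = sol.x[:n], sol.x[n:]
    res = _residual(params, z, y, a, variant)
    return FixedPointResult(y_s=y, a_s=a, method="root_find",
                            n_iter=int(sol.nfev), residual=res, converged=res < tol)


# ---------------------------------------------------------------------------
# 2D (one y, one a neuron) exhaustive enumeration
# ---------------------------------------------------------------------------

def _steady_a_2d(y: np.ndarray, w: float, b0sig: float) -> np.ndarray:
    """a at steady state given y: a = b0σ/sqrt(1 − w·y²) on the feasible set."""
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - w * np.asarray(y, dtype=float) ** 2
        a = np.where(denom > 0, b0sig / np.sqrt(np.abs(denom)), np.inf)
    return a


def find_fixed_points_2d(params: CircuitParams, z: float, variant: str = "general",
                         scan_points: int = 2001, classify: bool = True) -> list[FixedPointResult]:
    """Enumerate all fixed points of the 2D circuit by sign-change scan.

    Every steady state has a = b0σ/sqrt(1 − w y²) > 0, which for w > 0
    restricts y to |y| < 1/√w; the scalar equation
    F(y) = −y + b z + (1 − a(y))·wr·⟨y⟩ = 0 (⟨y⟩ = y, or ⌊y⌋ for the
    rectified variant) is scanned densely on that interval (log-refined
    near the boundaries, where F diverges) and each sign change is
    polished by bisection.  For w = 0 a generous finite bracket is used.
    Stability is classified from the 2×2 Jacobian eigenvalues.
    """
    if params.n != 1:
        raise ValueError("find_fixed_points_2d requires n = 1")
    if variant not in ("general", "rectified"):
        raise ValueError("variant must be 'general' or 'rectified'")
    z = float(np.asarray(z).reshape(()))
    wr = float(params.W_r[0, 0])
    w = float(params.W[0, 0])
    b, b0, sig = float(params.b[0]), float(params.b0[0]), float(params.sigma[0])
    b0sig = b0 * sig
    bz = b * z
    rect = variant == "rectified"

    def F(y):
        a = _steady_a_2d(y, w, b0sig)
        yy = np.maximum(y, 0.0) if rect else y
        return -y + bz + (1.0 - a) * wr * yy

    if w > 0:
        L = 1.0 / np.sqrt(w)
        interior = np.linspace(-L * (1 - 1e-6), L * (1 - 1e-6), scan_points)
        edge = L * (1.0 - np.geomspace(1e-14, 1e-6, 120))
        grid = np.unique(np.concatenate([-edge, interior, edge]))
    else:
        amin = min(b0sig, 1.0)
        L = 10.0 * max(abs(bz), 1.0) / max(abs(1.0 - wr * (1.0 - amin)), 1e-6)
        grid = np.linspace(-L, L, scan_points)
    vals = F(grid)
    finite = np.isfinite(vals)
    grid, vals = grid[finite], vals[finite]

    roots: list[float] = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(grid[i])
        elif v0 * v1 < 0:
            r = optimize.brentq(F, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
            roots.append(r)
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if w == 0 and len(roots) == 0:
        warnings.warn("2D scan bracket exhausted without a sign change", stacklevel=2)

    # dedupe
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-8 * max(1.0, abs(r)):
            uniq.append(r)

    results = []
    for y_r in uniq:
        a_r = float(_steady_a_2d(np.array(y_r), w, b0sig))
        fp = FixedPointResult(y_s=np.array([y_r]), a_s=np.array([a_r]), method="root_find",
                              residual=_residual(params, np.array([z]), np.array([y_r]),
                                                 np.array([a_r]), variant))
        if classify:
            from .stability import jacobian  # local import avoids a cycle
            J = jacobian(params, np.array([z]), fp, variant=variant)
            mre = float(np.max(np.linalg.eigvals(J).real))
            fp.max_real_eig = mre
            fp.stable = None if abs(mre) < 1e-9 else mre < -1e-9
        results.append(fp)
    return results
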