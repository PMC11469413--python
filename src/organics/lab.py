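"""Numerical experiments: integration, phase portraits, random circuits, sweeps.

The random-circuit sampler draws broad, positive, scale-controlled
parameters — time constants log-uniform on [1, 100] ms, gains and
semisaturation log-uniform on [0.1, 2], normalization weights |N(0,1)|/n,
recurrent weights N(0,1)/√n rescaled to a prescribed maximum singular
value, and an input drive uniform in direction with ‖z‖ ≤ 1 — the regime
under which the randomized stability sweeps probe the conjecture that a
spectral-norm-constrained recurrent circuit always possesses an
asymptotically stable fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .dynamics import get_rhs
from .fixed_points import find_fixed_points_2d, fixed_point_iteration, refine_fixed_point
from .params import CircuitParams, CircuitState
from .stability import jacobian

__all__ = [
    "Trajectory",
    "SweepResult",
    "integrate",
    "integrate_linearized",
    "phase_portrait_2d",
    "sample_random_circuit",
    "stability_sweep",
]

DIVERGENCE_NORM = 1e12


@dataclass
class Trajectory:
    t: np.ndarray
    y_hist: np.ndarray          # (timesteps, n)
    a_hist: np.ndarray
    method: str
    dt: float
    diverged: bool = False

    @property
    def final_state(self) -> CircuitState:
        return CircuitState(y=self.y_hist[-1].copy(), a=self.a_hist[-1].copy())


@dataclass
class SweepResult:
    n_trials: int
    n_stable: int
    smax: float
    records: list = field(default_factory=list)   # per-trial dicts

    @property
    def fraction_stable(self) -> float:
        return self.n_stable / self.n_trials


def integrate(params: CircuitParams, z: Union[np.ndarray, Callable[[float], np.ndarray]],
              init: CircuitState, dt: float, t_end: float, method: str = "rk4",
              variant: str = "general") -> Trajectory:
    """Fixed-step explicit integration (forward Euler or classical RK4).

    ``z`` may be a constant drive vector or a callable t ↦ z(t).  A step
    whose state norm exceeds 1e12 (or goes non-finite) truncates the
    trajectory with ``diverged=True`` — never silently.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    min_tau = float(min(params.tau_y.min(), params.tau_a.min()))
    if dt > min_tau / 2:
        warnings.warn(f"dt={dt} exceeds min(tau)/2={min_tau / 2}; explicit stepping may be "
                      "unstable for this stiff system", stacklevel=2)
    if method not in ("euler", "rk4"):
        raise ValueError("method must be 'euler' or 'rk4'")
    rhs = get_rhs(variant)
    z_fn = z if callable(z) else (lambda _t, _z=np.atleast_1d(np.asarray(z, float)): _z)

    n_steps = int(round(t_end / dt))
    t = np.arange(n_steps + 1) * dt
    y = np.empty((n_steps + 1, params.n))
    a = np.empty((n_steps + 1, params.n))
    y[0], a[0] = init.y, init.a
    diverged = False
    state = CircuitState(y=init.y.copy(), a=init.a.copy())

    for k in range(n_steps):
        tk = t[k]
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                if method == "euler":
                    d = rhs(state, params, z_fn(tk))
                    y_new = state.y + dt * d.y
                    a_new = state.a + dt * d.a
                else:
                    k1 = rhs(state, params, z_fn(tk))
                    s2 = CircuitState(y=state.y + 0.5 * dt * k1.y, a=state.a + 0.5 * dt * k1.a)
                    k2 = rhs(s2, params, z_fn(tk + 0.5 * dt))
                    s3 = CircuitState(y=state.y + 0.5 * dt * k2.y, a=state.a + 0.5 * dt * k2.a)
                    k3 = rhs(s3, params, z_fn(tk + 0.5 * dt))
                    s4 = CircuitState(y=state.y + dt * k3.y, a=state.a + dt * k3.a)
                    k4 = rhs(s4, params, z_fn(tk + dt))
                    y_new = state.y + dt / 6.0 * (k1.y + 2 * k2.y + 2 * k3.y + k4.y)
                    a_new = state.a + dt / 6.0 * (k1.a + 2 * k2.a + 2 * k3.a + k4.a)
        except ValueError:
            # an intermediate stage left the representable range
            t, y, a = t[: k + 1], y[: k + 1], a[: k + 1]
            diverged = True
            break
        if (not np.all(np.isfinite(y_new)) or not np.all(np.isfinite(a_new))
                or max(np.max(np.abs(y_new)), np.max(np.abs(a_new))) > DIVERGENCE_NORM):
            t, y, a = t[: k + 1], y[: k + 1], a[: k + 1]
            diverged = True
            break
        y[k + 1], a[k + 1] = y_new, a_new
        state = CircuitState(y=y_new, a=a_new)
    return Trajectory(t=t, y_hist=y, a_hist=a, method=method, dt=dt, diverged=diverged)


def integrate_linearized(J: np.ndarray, init: np.ndarray, dt: float, t_end: float) -> np.ndarray:
    """Exact stepping of the linearized flow δ̇ = Jδ via the matrix exponential."""
    from scipy.linalg import expm
    step = expm(J * dt)
    n_steps = int(round(t_end / dt))
    out = np.empty((n_steps + 1, init.shape[0]))
    out[0] = init
    for k in range(n_steps):
        out[k + 1] = step @ out[k]
    return out


@dataclass
class PhasePortrait:
    Y: np.ndarray
    A: np.ndarray
    dY: np.ndarray
    dA: np.ndarray
    y_nullcline: np.ndarray      # (points, 2) array of (y, a) samples with ẏ = 0
    a_nullcline: np.ndarray
    fixed_points: list


def _nullcline_points(Y, A, F):
    """Sign-change interpolation of F = 0 along both grid axes."""
    pts = []
    for arrs in ((Y, A, F), (Y.T, A.T, F.T)):
        Yg, Ag, Fg = arrs
        s = np.sign(Fg)
        flip = s[:, :-1] * s[:, 1:] < 0
        i, j = np.nonzero(flip)
        f0, f1 = Fg[i, j], Fg[i, j + 1]
        w = f0 / (f0 - f1)
        pts.append(np.column_stack([Yg[i, j] * (1 - w) + Yg[i, j + 1] * w,
                                    Ag[i, j] * (1 - w) + Ag[i, j + 1] * w]))
    return np.vstack(pts) if pts else np.empty((0, 2))


def phase_portrait_2d(params: CircuitParams, z: float, y_range=(-2.0, 2.0),
                      a_range=(-0.5, 2.0), grid_n: int = 41,
                      variant: str = "general") -> PhasePortrait:
    """Vector field, nullclines, and classified fixed points of the 2D circuit."""
    if params.n != 1:
        raise ValueError("phase_portrait_2d requires n = 1")
    rhs = get_rhs(variant)
    yv = np.linspace(*y_range, grid_n)
    av = np.linspace(*a_range, grid_n)
    Y, A = np.meshgrid(yv, av)
    dY = np.empty_like(Y)
    dA = np.empty_like(A)
    zvec = np.array([float(z)])
    for idx in np.ndindex(Y.shape):
        d = rhs(CircuitState(y=np.array([Y[idx]]), a=np.array([A[idx]])), params, zvec)
        dY[idx], dA[idx] = d.y[0], d.a[0]
    fps = find_fixed_points_2d(params, z, variant=variant)
    return PhasePortrait(Y=Y, A=A, dY=dY, dA=dA,
                         y_nullcline=_nullcline_points(Y, A, dY),
                         a_nullcline=_nullcline_points(Y, A, dA),
                         fixed_points=fps)


def sample_random_circuit(n: int, smax: float = 1.0, rng_seed=0,
                          identity_recurrence: bool = False,
                          w_scale: Union[float, str] = 1.0) -> tuple[CircuitParams, np.ndarray]:
    """Draw a random circuit and input under the sweep constraints.

    Guarantees ‖z‖₂ ≤ 1 and max singular value of W_r equal to ``smax``
    exactly (spectral rescaling); W is nonnegative with entries |N(0,1)|/n,
    optionally multiplied by ``w_scale`` (or a log-uniform [0.1, 10] factor
    when ``w_scale="random"``, to exercise the unconstrained-pool regime).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    loguni = lambda lo, hi, size: np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    tau_y = loguni(1.0, 100.0, n)
    tau_a = loguni(1.0, 100.0, n)
    b = loguni(0.1, 2.0, n)
    b0 = loguni(0.1, 2.0, n)
    sigma = loguni(0.1, 2.0, n)
    scale = loguni(0.1, 10.0, ()) if w_scale == "random" else float(w_scale)
    W = np.abs(rng.standard_normal((n, n))) / n * scale
    if identity_recurrence:
        W_r = np.eye(n)
    else:
        W_r = rng.standard_normal((n, n)) / np.sqrt(n)
        W_r *= smax / np.linalg.svd(W_r, compute_uv=False)[0]
    direction = rng.standard_normal(n)
    direction /= np.linalg.norm(direction)
    z = direction * rng.uniform(0.0, 1.0)
    params = CircuitParams(n=n, tau_y=tau_y, tau_a=tau_a, b=b, b0=b0, sigma=sigma,
                           W_r=W_r, W=W)
    return params, z


def _max_real_at(params: CircuitParams, z: np.ndarray, fp) -> float:
    J = jacobian(params, z, fp, variant="general")
    return float(np.max(np.linalg.eigvals(J).real))


def _locate_and_classify(params: CircuitParams, z: np.ndarray, tol: float = 1e-6):
    """Locate a fixed point by iteration, with a long-integration fallback.

    The fallback (integrate from rest, then Newton-polish the endpoint)
    also runs when the iteration converged onto an *unstable* fixed point:
    with expansive recurrence the circuit can have several equilibria, and
    the claim under test is that a stable one exists, which is where the
    dynamics themselves settle.
    """
    fp = fixed_point_iteration(params, z, tol=tol, max_iter=50)
    if fp.converged:
        mre = _max_real_at(params, z, fp)
        if mre < -1e-9:
            return fp, mre
    else:
        mre = np.inf
    init = CircuitState(y=np.zeros(params.n), a=params.b0 * params.sigma)
    tau_max = float(max(params.tau_y.max(), params.tau_a.max()))
    traj = integrate(params, z, init, dt=min(params.tau_y.min(), params.tau_a.min()) / 3,
                     t_end=40 * tau_max, method="rk4", variant="general")
    if not traj.diverged:
        fs = traj.final_state
        fp2 = refine_fixed_point(params, z, fs.y, fs.a, variant="general", tol=tol)
        if fp2.converged:
            mre2 = _max_real_at(params, z, fp2)
            if mre2 < mre or not fp.converged:
                return fp2, mre2
    return fp, (mre if fp.converged else np.inf)


def stability_sweep(n: int, n_trials: int, smax: float, rng_seed: int = 0,
                    identity_recurrence: bool = False) -> SweepResult:
    """Randomized stability sweep: fraction of trials with a stable located fixed point.

    A trial counts as stable only if the fixed-point search converged and
    the maximum real part of the Jacobian spectrum there is below −1e−9;
    diverged or non-converged trials count as unstable, never dropped.
    Fully reproducible from (n, n_trials, smax, rng_seed).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_trials)
    records = []
    n_stable = 0
    for trial, seed in enumerate(seeds):
        params, z = sample_random_circuit(n, smax=smax, rng_seed=int(seed),
                                          identity_recurrence=identity_recurrence)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fp, max_real = _locate_and_classify(params, z)
        stable = bool(fp.converged and max_real < -1e-9)
        n_stable += stable
        records.append({"trial": trial, "seed": int(seed), "max_real_eig": max_real,
                        "converged": fp.converged, "n_iter": fp.n_iter, "stable": stable})
    return SweepResult(n_trials=n_trials, n_stable=n_stable, smax=smax, records=records)
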