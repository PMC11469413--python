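"""Local stability certificates for the circuit.

Linearizing the identity-recurrence circuit about its normalization fixed
point and eliminating the modulator block turns the characteristic
polynomial into a quadratic eigenvalue problem (QEP)

    det(λ²I + λB + K) = 0,

the characteristic problem of a coupled damped harmonic oscillator
Iẍ + Bẋ + Kx = 0 with positive diagonal stiffness

    K = D(a_s ⊘ (τy⊙τa))

and damping

    B = B1 + B2 − B3 = D(1⊘τa) + D(a_s⊘τy) − D(1⊘τa) W D(y_s²).

B is a Z-matrix (nonpositive off-diagonals) and admits the regular
splitting B = M − N with M = B1 + B2, N = B3.  The iteration matrix
S = M⁻¹N has spectral radius < 1 for every admissible parameter set and
input — the saturating structure W D(u/(v+Wu)) with u = b²⊙z², v = b0²⊙σ²
caps it — so B is a nonsingular M-matrix, hence Lyapunov diagonally
stable: there is a positive diagonal T with TB + BᵀT ≻ 0.  That certifies
asymptotic stability of the oscillator system and therefore of the
circuit's linearization, unconditionally in the parameters and input.

The Jacobian implemented here is derived from the adopted right-hand
sides; its spectrum coincides with the QEP spectrum through the diagonal
similarity B̃ = D(a_s)⁻¹ B D(a_s) (K is diagonal and unaffected), a fact
the test suite enforces numerically rather than assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .dynamics import modulator_drive
from .fixed_points import FixedPointResult, analytic_fixed_point, fixed_point_iteration, refine_fixed_point
from .params import CircuitParams, CircuitState, rectify

__all__ = [
    "QEPMatrices",
    "SplittingCertificate",
    "StabilityReport",
    "jacobian",
    "qep_matrices",
    "qep_eigenvalues",
    "splitting_certificate",
    "special_case_eigenvalues",
    "assess_stability",
    "eigs_match",
]

_CORNER_TOL = 1e-9
_STAB_TOL = 1e-9


@dataclass
class QEPMatrices:
    """Damping/stiffness matrices of the oscillator reduction."""

    B: np.ndarray
    K: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    B3: np.ndarray


@dataclass
class SplittingCertificate:
    """Regular-splitting and diagonal-Lyapunov certificates for B."""

    M: np.ndarray
    N: np.ndarray
    S: np.ndarray
    rho: float                # spectral radius of S = M⁻¹N
    is_Z: bool                # B has nonpositive off-diagonal entries
    is_M_matrix: bool         # Z-matrix with convergent splitting
    T_diag: np.ndarray        # positive diagonal Lyapunov witness
    witness_min_eig: float    # smallest eigenvalue of TB + BᵀT
    witness_ok: bool

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "is_Z": self.is_Z,
            "is_M_matrix": self.is_M_matrix,
            "T_diag": self.T_diag.tolist(),
            "witness_min_eig": self.witness_min_eig,
            "witness_ok": self.witness_ok,
        }


@dataclass
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    max_real: float
    stable: bool
    fixed_point: FixedPointResult
    qep: Optional[QEPMatrices] = None
    qep_eigenvalues: Optional[np.ndarray] = None
    certificate: Optional[SplittingCertificate] = None

    def to_dict(self) -> dict:
        d = {
            "eigenvalues": [[float(v.real), float(v.imag)] for v in self.eigenvalues],
            "max_real": self.max_real,
            "stable": self.stable,
            "fixed_point": self.fixed_point.to_dict(),
        }
        if self.certificate is not None:
            d["certificate"] = self.certificate.to_dict()
        return d


def _state_of(point: Union[FixedPointResult, CircuitState]) -> CircuitState:
    return point.state if isinstance(point, FixedPointResult) else point


def jacobian(params: CircuitParams, z: np.ndarray, point: Union[FixedPointResult, CircuitState],
             variant: str = "identity") -> np.ndarray:
    """Analytic 2n×2n Jacobian of the chosen RHS at a state.

    Valid away from the rectification corners a_i = 0 (and y_i = 0 for the
    rectified variant); a warning is issued when a corner is within 1e−9.
    """
    st = _state_of(point)
    y, a = st.y, st.a
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n = params.n
    ty, ta = params.tau_y, params.tau_a
    if np.any(np.abs(a) < _CORNER_TOL) or (variant == "rectified" and np.any(np.abs(y) < _CORNER_TOL)):
        warnings.warn("state sits on a rectification corner; Jacobian uses the one-sided "
                      "derivative with subgradient 0 at the corner", stacklevel=2)
    a_pos = (a > 0).astype(float)
    ap = rectify(a)

    if variant == "identity":
        dydy = np.diag(-ap / ty)
        dyda = np.diag(-y / ty * a_pos)
    elif variant == "general":
        dydy = (-np.eye(n) + (1.0 - ap)[:, None] * params.W_r) / ty[:, None]
        dyda = np.diag(-(params.W_r @ y) / ty * a_pos)
    elif variant == "rectified":
        y_pos = (y > 0).astype(float)
        dydy = (-np.eye(n) + (1.0 - ap)[:, None] * params.W_r * y_pos[None, :]) / ty[:, None]
        dyda = np.diag(-(params.W_r @ rectify(y)) / ty * a_pos)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    s = modulator_drive(y, a, params)
    dady = (params.W * (y * ap**2)[None, :]) / (s[:, None] * ta[:, None])
    dada = (-np.eye(n) + (params.W * (y**2 * ap)[None, :]) * a_pos[None, :] / s[:, None]) / ta[:, None]
    return np.block([[dydy, dyda], [dady, dada]])


def qep_matrices(params: CircuitParams, z: np.ndarray) -> QEPMatrices:
    """Damping and stiffness matrices B, K at the normalization fixed point (W_r = I)."""
    fp = analytic_fixed_point(params, z)   # validates W_r = I
    a_s, y_s = fp.a_s, fp.y_s
    ty, ta = params.tau_y, params.tau_a
    B1 = np.diag(1.0 / ta)
    B2 = np.diag(a_s / ty)
    B3 = (params.W * (y_s**2)[None, :]) / ta[:, None]
    K = np.diag(a_s / (ty * ta))
    return QEPMatrices(B=B1 + B2 - B3, K=K, B1=B1, B2=B2, B3=B3)


def qep_eigenvalues(qep: QEPMatrices) -> np.ndarray:
    """All 2n roots of det(λ²I + λB + K) via companion-form linearization."""
    n = qep.B.shape[0]
    companion = np.block([[np.zeros((n, n)), np.eye(n)], [-qep.K, -qep.B]])
    return np.linalg.eigvals(companion)


def splitting_certificate(qep: QEPMatrices, tol: float = 1e-12) -> SplittingCertificate:
    """Regular splitting B = (B1+B2) − B3 and a diagonal Lyapunov witness.

    The witness is the standard M-matrix construction T = D(v ⊘ u) with
    u = B⁻¹1 and v = B⁻ᵀ1 (both elementwise positive for a nonsingular
    M-matrix); positive definiteness of TB + BᵀT is verified numerically
    and reported, never assumed.
    """
    B, M, N = qep.B, qep.B1 + qep.B2, qep.B3
    n = B.shape[0]
    S = np.linalg.solve(M, N)
    rho = float(np.max(np.abs(np.linalg.eigvals(S)))) if n > 0 else 0.0
    off = B - np.diag(np.diag(B))
    is_Z = bool(np.all(off <= tol))
    is_M = bool(is_Z and rho < 1.0)
    ones = np.ones(n)
    try:
        u = np.linalg.solve(B, ones)
        v = np.linalg.solve(B.T, ones)
    except np.linalg.LinAlgError:
        u = v = np.full(n, np.nan)
    if np.all(u > 0) and np.all(v > 0):
        T = v / u
    else:
        T = np.ones(n)   # fallback witness; verification below decides
    TB = T[:, None] * B
    sym = TB + TB.T
    wmin = float(np.min(np.linalg.eigvalsh(sym)))
    return SplittingCertificate(M=M, N=N, S=S, rho=rho, is_Z=is_Z, is_M_matrix=is_M,
                                T_diag=T, witness_min_eig=wmin, witness_ok=wmin > 0)


def special_case_eigenvalues(params: CircuitParams, z: np.ndarray) -> np.ndarray:
    """Closed-form spectrum for W = α·E (all-ones pool), W_r = I, scalar parameters.

    B is then diagonal-plus-rank-one, B = cI − (α/τa)·1·(y_s²)ᵀ with
    c = 1/τa + a_s/τy, and K = kI with k = a_s/(τy·τa); the QEP decouples
    in the eigenbasis of B into n scalar quadratics: λ² + cλ + k = 0 with
    multiplicity n−1, and λ² + (c − (α/τa)·Σᵢ y_sᵢ²)λ + k = 0 once.
    """
    n = params.n
    for name in ("tau_y", "tau_a", "b", "b0", "sigma"):
        vec = getattr(params, name)
        if not np.allclose(vec, vec[0]):
            raise ValueError(f"special case requires scalar {name}")
    if not params.identity_recurrence:
        raise ValueError("special case requires W_r = I")
    alpha = params.W[0, 0]
    if not np.allclose(params.W, alpha):
        raise ValueError("special case requires W = alpha * all-ones matrix")
    z = np.atleast_1d(np.asarray(z, dtype=float))
    ty, ta = params.tau_y[0], params.tau_a[0]
    bz2 = (params.b * z) ** 2
    a_s = float(np.sqrt((params.b0[0] * params.sigma[0]) ** 2 + alpha * np.sum(bz2)))
    ys2_sum = float(np.sum(bz2)) / a_s**2
    c = 1.0 / ta + a_s / ty
    k = a_s / (ty * ta)

    def quad_roots(damping: float) -> np.ndarray:
        disc = complex(damping * damping - 4.0 * k)
        sq = np.sqrt(disc)
        return np.array([(-damping + sq) / 2.0, (-damping - sq) / 2.0])

    lams = [quad_roots(c) for _ in range(n - 1)]
    lams.append(quad_roots(c - (alpha / ta) * ys2_sum))
    return np.concatenate(lams)


def assess_stability(params: CircuitParams, z: np.ndarray, variant: str = "general",
                     tol: float = 1e-8, max_iter: int = 50) -> StabilityReport:
    """Full stability report at the circuit's (located) fixed point.

    Identity-recurrence circuits get the closed-form fixed point plus the
    QEP matrices and M-matrix/Lyapunov certificates; otherwise the fixed
    point is located by the alternating iteration with a Newton fallback.
    Non-convergence is reported as unstable, never dropped.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    qep = qep_eigs = cert = None
    if variant == "identity" or (variant == "general" and params.identity_recurrence):
        fp = analytic_fixed_point(params, z)
        jac_variant = "identity"
        qep = qep_matrices(params, z)
        qep_eigs = qep_eigenvalues(qep)
        cert = splitting_certificate(qep)
    else:
        fp = fixed_point_iteration(params, z, tol=tol, max_iter=max_iter)
        if not fp.converged:
            fp = refine_fixed_point(params, z, fp.y_s, fp.a_s, variant=variant, tol=tol)
        jac_variant = variant
    J = jacobian(params, z, fp, variant=jac_variant)
    eigs = np.linalg.eigvals(J)
    max_real = float(np.max(eigs.real))
    stable = bool(fp.converged and max_real < -_STAB_TOL)
    fp.stable = stable
    fp.max_real_eig = max_real
    return StabilityReport(jacobian=J, eigenvalues=eigs, max_real=max_real, stable=stable,
                           fixed_point=fp, qep=qep, qep_eigenvalues=qep_eigs, certificate=cert)


def eigs_match(e1: np.ndarray, e2: np.ndarray, tol: float = 1e-6) -> bool:
    """Multiset equality of two spectra: sort by (Re, Im), compare with per-root tolerance."""
    e1 = np.sort_complex(np.asarray(e1, dtype=complex))
    e2 = np.sort_complex(np.asarray(e2, dtype=complex))
    if e1.shape != e2.shape:
        return False
    return bool(np.all(np.abs(e1 - e2) <= tol * (1.0 + np.abs(e2))))
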