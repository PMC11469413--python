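"""Discrete-time differentiable cell: explicit Euler steps of the rectified
circuit with dynamic input gains, trainable by plain backpropagation
through time.

One step advances (y, a, b, b0) simultaneously, using the pre-update
values on every right-hand side:

    z    = W_zx x_t
    y ←  y + (dt⊘τy) ⊙ (−y + b⊙z + (1−⌊a⌋) ⊙ (W_r ⌊y⌋))
    a ←  a + (dt⊘τa) ⊙ (−a + sqrt((b0⊙σ)² + W(y²⊙⌊a⌋²)))
    b ←  b + (dt⊘τb) ⊙ (−b + f(W_bx x_t + W_by y + W_ba a))
    b0 ← b0 + (dt⊘τb0) ⊙ (−b0 + f(W_b0x x_t + W_b0y y + W_b0a a))

The gain nonlinearity f is the logistic sigmoid (range (0,1)): gains stay
positive and bounded, mirroring the recurrent-gain convention 1−a⁺.  The
normalization pool is parameterized as W = W_raw² elementwise so it stays
nonnegative under gradient descent (keeping the square root's argument
nonnegative), and learnable time constants use τ = dt + softplus(θ), which
lower-bounds them by the step size.  Rectification uses subgradient 0 at
the corner.  Training applies raw stochastic-gradient updates — no
gradient clipping or rescaling anywhere — which the circuit's intrinsic
stability makes viable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["CellWeights", "CellState", "cell_step", "run_sequence", "train_toy", "TrainResult"]


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


@dataclass
class CellWeights:
    """Trainable parameters of the cell; arrays live in autodiff Tensors."""

    n: int
    m: int
    n_classes: int
    dt: float
    sigma: Tensor
    W_zx: Tensor
    W_r: Tensor
    W_raw: Tensor                 # normalization pool is W_raw² ≥ 0
    theta_tau_y: Tensor           # τ = dt + softplus(θ)
    theta_tau_a: Tensor
    theta_tau_b: Tensor
    theta_tau_b0: Tensor
    W_bx: Tensor
    W_by: Tensor
    W_ba: Tensor
    W_b0x: Tensor
    W_b0y: Tensor
    W_b0a: Tensor
    readout: Tensor               # (classes, n)
    readout_bias: Tensor
    learn_time_constants: bool = True
    learn_gains: bool = True      # when False, b and b0 stay at their initial values

    @classmethod
    def init(cls, n: int, m: int, n_classes: int, dt: float = 1.0, seed: int = 0,
             learn_time_constants: bool = True, learn_gains: bool = True,
             tau_init: Optional[np.ndarray] = None) -> "CellWeights":
        """Initialize at the provably stable point: W_r = I, modest pool weights.

        Time constants default to a spread uniform on [2, 8]·dt so neurons
        integrate at a mix of timescales.
        """
        rng = np.random.default_rng(seed)
        if tau_init is None:
            tau_init = rng.uniform(2.0, 8.0, n) * dt

        def mat(rows, cols, scale):
            return Tensor(rng.standard_normal((rows, cols)) * scale, requires_grad=True)

        col = lambda v: Tensor(np.asarray(v, float)[:, None], requires_grad=True)
        return cls(
            n=n, m=m, n_classes=n_classes, dt=float(dt),
            sigma=col(np.full(n, 0.5)),
            W_zx=mat(n, m, 1.0 / np.sqrt(m)),
            W_r=Tensor(np.eye(n), requires_grad=True),
            W_raw=Tensor(np.eye(n), requires_grad=True),
            theta_tau_y=col(_inv_softplus(tau_init - dt)),
            theta_tau_a=col(_inv_softplus(rng.uniform(2.0, 8.0, n) * dt - dt)),
            theta_tau_b=col(_inv_softplus(rng.uniform(2.0, 8.0, n) * dt - dt)),
            theta_tau_b0=col(_inv_softplus(rng.uniform(2.0, 8.0, n) * dt - dt)),
            W_bx=mat(n, m, 1.0 / np.sqrt(m)),
            W_by=mat(n, n, 1.0 / np.sqrt(n)),
            W_ba=mat(n, n, 1.0 / np.sqrt(n)),
            W_b0x=mat(n, m, 1.0 / np.sqrt(m)),
            W_b0y=mat(n, n, 1.0 / np.sqrt(n)),
            W_b0a=mat(n, n, 1.0 / np.sqrt(n)),
            readout=mat(n_classes, n, 1.0 / np.sqrt(n)),
            readout_bias=Tensor(np.zeros((n_classes, 1)), requires_grad=True),
            learn_time_constants=learn_time_constants,
            learn_gains=learn_gains,
        )

    def trainable(self) -> dict[str, Tensor]:
        named = {k: getattr(self, k) for k in (
            "sigma", "W_zx", "W_r", "W_raw", "W_bx", "W_by", "W_ba",
            "W_b0x", "W_b0y", "W_b0a", "readout", "readout_bias")}
        if self.learn_time_constants:
            named.update({k: getattr(self, k) for k in
                          ("theta_tau_y", "theta_tau_a", "theta_tau_b", "theta_tau_b0")})
        return named

    def tau(self, which: str) -> Tensor:
        theta = getattr(self, f"theta_tau_{which}")
        if self.learn_time_constants:
            return ad.softplus(theta) + self.dt
        return Tensor(np.logaddexp(0.0, theta.data) + self.dt)

    @property
    def W(self) -> Tensor:
        return ad.square(self.W_raw)


@dataclass
class CellState:
    """Hidden state at one step; columns are batch elements."""

    y: Tensor
    a: Tensor
    b: Tensor
    b0: Tensor


def init_state(weights: CellWeights, batch: int, rng: np.random.Generator,
               init_policy: str = "uniform") -> CellState:
    """Hidden potentials y, a ~ U[0, 0.1]; gains start at f(0) = 1/2."""
    if init_policy == "uniform":
        y0 = rng.uniform(0.0, 0.1, (weights.n, batch))
        a0 = rng.uniform(0.0, 0.1, (weights.n, batch))
    elif init_policy == "zeros":
        y0 = np.zeros((weights.n, batch))
        a0 = np.zeros((weights.n, batch))
    else:
        raise ValueError(f"unknown init_policy {init_policy!r}")
    half = np.full((weights.n, batch), 0.5)
    return CellState(y=Tensor(y0), a=Tensor(a0), b=Tensor(half.copy()), b0=Tensor(half.copy()))


def cell_step(state: CellState, x_t, weights: CellWeights) -> CellState:
    """One explicit-Euler update of (y, a, b, b0); fully differentiable."""
    x_t = ad.as_tensor(x_t)
    y, a, b, b0 = state.y, state.a, state.b, state.b0
    dt = weights.dt
    z = weights.W_zx @ x_t
    a_plus = ad.relu(a)
    y_plus = ad.relu(y)
    recur = (1.0 - a_plus) * (weights.W_r @ y_plus)
    y_new = y + (dt / weights.tau("y")) * (-y + b * z + recur)
    drive = ad.sqrt(ad.square(b0 * weights.sigma) + weights.W @ (ad.square(y) * ad.square(a_plus)))
    a_new = a + (dt / weights.tau("a")) * (-a + drive)
    if weights.learn_gains:
        b_new = b + (dt / weights.tau("b")) * (
            -b + ad.sigmoid(weights.W_bx @ x_t + weights.W_by @ y + weights.W_ba @ a))
        b0_new = b0 + (dt / weights.tau("b0")) * (
            -b0 + ad.sigmoid(weights.W_b0x @ x_t + weights.W_b0y @ y + weights.W_b0a @ a))
    else:
        b_new, b0_new = b, b0
    for t in (y_new, a_new, b_new, b0_new):
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError("non-finite cell state")
    return CellState(y=y_new, a=a_new, b=b_new, b0=b0_new)


def run_sequence(x_seq: np.ndarray, weights: CellWeights,
                 init_policy: str = "uniform", rng=None) -> tuple[CellState, Tensor]:
    """Iterate the cell over a (T, m, batch) sequence; logits read out the final y."""
    x_seq = np.asarray(x_seq, dtype=float)
    if x_seq.ndim == 2:
        x_seq = x_seq[:, :, None]
    if x_seq.shape[0] == 0:
        raise ValueError("sequence must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    state = init_state(weights, x_seq.shape[2], rng, init_policy)
    for t in range(x_seq.shape[0]):
        state = cell_step(state, x_seq[t], weights)
    logits = weights.readout @ state.y + weights.readout_bias
    return state, logits


@dataclass
class TrainResult:
    loss_history: np.ndarray
    grad_norm_history: np.ndarray
    final_accuracy: float
    weights: CellWeights


def train_toy(task: str = "delayed-recall", steps: int = 2000, lr: float = 0.01,
              seed: int = 0, n: int = 16, seq_len: int = 32, batch_size: int = 32,
              n_examples: int = 2000, dt: float = 1.0,
              learn_time_constants: bool = True,
              on_gradient: Optional[Callable[[dict], None]] = None) -> TrainResult:
    """Train the cell on a synthetic sequence task by naive BPTT.

    Plain SGD on the raw gradients: no clipping, no rescaling, no
    momentum.  Every gradient is checked finite at every step; a
    non-finite loss or gradient aborts with a diagnostic, since bounded
    gradients under naive BPTT are exactly the property the circuit's
    stability is meant to buy.  ``on_gradient`` (optional) observes the
    raw gradient dict each step; its return value is ignored, so it
    cannot alter the update.
    """
    from .tasks import make_task

    rng = np.random.default_rng(seed)
    X, labels, n_classes, m = make_task(task, n_examples=n_examples, seq_len=seq_len, rng=rng)
    weights = CellWeights.init(n=n, m=m, n_classes=n_classes, dt=dt,
                               seed=int(rng.integers(2**31)),
                               learn_time_constants=learn_time_constants)
    named = weights.trainable()
    losses = np.empty(steps)
    gnorms = np.empty(steps)
    for step in range(steps):
        idx = rng.integers(0, n_examples, batch_size)
        xb = np.transpose(X[idx], (1, 2, 0))     # (T, m, batch)
        for p in named.values():
            p.zero_grad()
        _, logits = run_sequence(xb, weights, rng=rng)
        loss = ad.cross_entropy_logits(logits, labels[idx])
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at step {step}")
        loss.backward()
        grads = {k: p.grad for k, p in named.items()}
        for k, g in grads.items():
            if g is None or not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for {k} at step {step}")
        if on_gradient is not None:
            on_gradient(grads)
        for k, p in named.items():
            p.data = p.data - lr * grads[k]      # raw update: no clip, no scale
        losses[step] = loss.data
        gnorms[step] = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    # held-out-ish accuracy on a fresh batch of the generator
    Xe, ye, _, _ = make_task(task, n_examples=256, seq_len=seq_len, rng=rng)
    _, logits = run_sequence(np.transpose(Xe, (1, 2, 0)), weights, rng=rng)
    acc = float(np.mean(np.argmax(logits.data, axis=0) == ye))
    return TrainResult(loss_history=losses, grad_norm_history=gnorms,
                       final_accuracy=acc, weights=weights)
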